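#!/usr/bin/env python
"""Download the benchmark crystal structures from the PDB (network needed).

Usage::

    python scripts/fetch_benchmark_structures.py [--out benchmarks/structures]

Fetches the five HLA-A*0201 validation entries (1HHG 1HHH 1HHI 1HHJ 1HHK),
the HLA-DR15 frames (1YMM 1BX2) and the seventeen HLA-A2 entries of the
reference-set study.  The test suite and acceptance script never require
these files; the published-value benchmark test uses them when present.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

from groovescore.benchmarks import MADDEN_IDS
from groovescore.data import a2_structure_pairs

URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path,
                        default=Path("benchmarks/structures"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    wanted = list(MADDEN_IDS) + ["1YMM", "1BX2", "1FYT", "1J8H", "2GTW"]
    wanted += [pdb_id for pdb_id, _ in a2_structure_pairs()]
    for pdb_id in dict.fromkeys(wanted):
        target = args.out / f"{pdb_id}.pdb"
        if target.exists():
            print(f"{pdb_id}: already present")
            continue
        print(f"{pdb_id}: downloading")
        with urllib.request.urlopen(URL.format(pdb_id=pdb_id)) as resp:
            target.write_bytes(resp.read())


if __name__ == "__main__":
    main()
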