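"""Published-benchmark runners over locally provided crystal structures.

These routines reproduce the validation experiments on real PDB entries:
the five HLA-A*0201 complexes solved by Madden and co-workers scored
natively against their experimental binding free energies, and the HLA-DR15
run threading the twenty 14-mer binders onto the 1YMM frame.  Crystal
structures are not redistributed with the package; download the entries
from the PDB (e.g. with ``scripts/fetch_benchmark_structures.py``) into a
directory and pass its path.
"""

from __future__ import annotations

from pathlib import Path

from .data import load_dr15_records, load_madden_dg
from .errors import DataError
from .pipeline import prepare_complex, run_train_predict, run_validate
from .refsets import mean_pairwise_rmsd

#: Class I entries: heavy chain + beta-2-microglobulin frame, peptide chain C.
CLASS_I_CHAINS = {"A": "mhc", "B": "mhc", "C": "peptide"}
#: Class II entries: alpha + beta chains, peptide chain C.
CLASS_II_CHAINS = {"A": "mhc", "B": "mhc", "C": "peptide"}

MADDEN_IDS = ("1HHG", "1HHH", "1HHI", "1HHJ", "1HHK")


def _load(structures_dir: str | Path, pdb_id: str, chains: dict):
    path = Path(structures_dir) / f"{pdb_id}.pdb"
    if not path.exists():
        raise DataError(
            f"structure file {path} not found; download {pdb_id} from the "
            "PDB into that directory first"
        )
    return prepare_complex(path.read_text(), chains, pdb_id)


def run_madden_validation(structures_dir: str | Path) -> dict:
    """Native-complex validation on the five Madden HLA-A2 structures.

    Returns the run_validate report plus the mean pairwise whole-structure
    RMSD of the five complexes.
    """
    complexes = [
        _load(structures_dir, pdb_id, CLASS_I_CHAINS)
        for pdb_id in MADDEN_IDS
    ]
    table = load_madden_dg()
    dg_by_id = dict(zip(table["pdb_id"], table["dg_exp_kJ_mol"]))
    report = run_validate(complexes, dg_by_id)
    report["mean_pairwise_rmsd"] = mean_pairwise_rmsd(complexes, "whole")
    return report


def run_dr15_benchmark(structures_dir: str | Path, pdb_id: str = "1YMM") -> dict:
    """Thread the twenty 14-mer DR15 binders onto one class II frame."""
    reference = _load(structures_dir, pdb_id, CLASS_II_CHAINS)
    return run_train_predict(reference, load_dr15_records())
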