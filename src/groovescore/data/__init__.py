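"""Bundled reference tables.

Published per-peptide binding data for the HLA alleles studied with this
scoring function: the five HLA-A*0201 validation complexes with their
experimental binding free energies, the twenty 14-mer HLA-DR15 binders
(IC50 in nanomolar at 37 degrees C), and the seventeen HLA-A2 crystal
structures with native-peptide binding data (IC50 declared molar; any
constant unit factor only shifts every dG by the same additive amount,
which the regression intercept absorbs).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from ..affinity import BindingRecord, load_binding_table


def _read_text(name: str) -> str:
    return (
        importlib.resources.files(__package__).joinpath(name).read_text()
    )


def load_madden_dg() -> pd.DataFrame:
    """Five HLA-A*0201 validation complexes with experimental dG (kJ/mol)."""
    import io

    return pd.read_csv(io.StringIO(_read_text("table1_madden.tsv")), sep="\t")


def load_dr15_records() -> list[BindingRecord]:
    """Twenty 14-mer HLA-DR15 binders (IC50 nM, 37 C) as BindingRecords."""
    return load_binding_table(
        _read_text("table2_dr15.tsv"), unit="nM", allele="HLA-DRB1*1501"
    )


def load_a2_structure_table() -> pd.DataFrame:
    """Seventeen HLA-A2 entries: peptide, temperature, IC50, PDB id."""
    import io

    return pd.read_csv(io.StringIO(_read_text("table3_a2.tsv")), sep="\t")


def a2_structure_pairs() -> list[tuple[str, str]]:
    """(pdb_id, native peptide) pairs for reference-set enumeration."""
    frame = load_a2_structure_table()
    return list(zip(frame["pdb_id"], frame["peptide"]))


def load_a2_records() -> list[BindingRecord]:
    """Native-peptide binding records for the seventeen HLA-A2 entries."""
    frame = load_a2_structure_table().drop_duplicates("peptide")
    text = "peptide\tic50\ttemperature\n" + "\n".join(
        f"{r.peptide}\t{r.ic50}\t{r.temperature}"
        for r in frame.itertuples()
    )
    return load_binding_table(text, unit="M", allele="HLA-A*0201")
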