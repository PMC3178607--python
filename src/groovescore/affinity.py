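"""Binding-data curation and IC50 to free-energy conversion.

At low peptide concentration the IC50 of a competitive binding assay
approximates the dissociation constant, so the binding free energy is
dG = R * T * ln(IC50) with IC50 in molar and T the assay temperature in
Kelvin.  Units are never guessed: every table declares its IC50 unit.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from ._chemdata import AA1_TO_3
from .errors import DataError

#: Gas constant, J mol^-1 K^-1
R_GAS = 8.314462

CELSIUS_OFFSET = 273.15

UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


@dataclass
class BindingRecord:
    """One peptide with measured IC50 (molar), assay temperature (Celsius)
    and the derived binding free energy (kJ/mol)."""

    peptide_sequence: str
    ic50: float
    temperature: float
    dg_bind: float
    source_tag: str = ""
    allele: str = ""

    def __post_init__(self):
        if not self.peptide_sequence:
            raise DataError("empty peptide sequence")
        bad = [x for x in self.peptide_sequence if x not in AA1_TO_3]
        if bad:
            raise DataError(
                f"non-standard letters {bad} in {self.peptide_sequence!r}"
            )


def deltaG_from_ic50(ic50: float, temperature: float) -> float:
    """kJ/mol from IC50 in molar and temperature in Celsius."""
    if ic50 <= 0:
        raise DataError(f"IC50 must be positive, got {ic50}")
    t_kelvin = temperature + CELSIUS_OFFSET
    return R_GAS * t_kelvin * math.log(ic50) / 1000.0


def make_record(
    peptide: str, ic50_molar: float, temperature: float,
    source_tag: str = "", allele: str = "",
) -> BindingRecord:
    return BindingRecord(
        peptide_sequence=peptide,
        ic50=ic50_molar,
        temperature=temperature,
        dg_bind=deltaG_from_ic50(ic50_molar, temperature),
        source_tag=source_tag,
        allele=allele,
    )


def load_binding_table(
    tsv_text: str, unit: str, allele: str = ""
) -> list[BindingRecord]:
    """Parse a TSV with columns peptide, ic50, temperature[, source].

    `unit` declares the IC50 unit of the whole file (e.g. ``nM``); values
    are converted to molar.  Exact duplicate (sequence, ic50, temperature)
    rows are collapsed with a warning.
    """
    if unit not in UNIT_FACTORS:
        raise DataError(
            f"unknown IC50 unit {unit!r}; one of {sorted(UNIT_FACTORS)}"
        )
    factor = UNIT_FACTORS[unit]
    try:
        frame = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    frame.columns = [str(col).strip().lower() for col in frame.columns]
    for required in ("peptide", "ic50", "temperature"):
        if required not in frame.columns:
            raise DataError(f"missing required column {required!r}")

    records: list[BindingRecord] = []
    seen: set[tuple] = set()
    for idx, row in frame.iterrows():
        row_no = idx + 2  # 1-based, after the header line
        peptide = str(row["peptide"]).strip()
        try:
            ic50 = float(row["ic50"])
            temperature = float(row["temperature"])
        except (TypeError, ValueError) as exc:
            raise DataError(f"unparsable numeric value in row {row_no}") from exc
        key = (peptide, ic50, temperature)
        if key in seen:
            warnings.warn(f"duplicate row {row_no} for {peptide} collapsed")
            continue
        seen.add(key)
        source = str(row.get("source", "") or "")
        try:
            records.append(
                make_record(peptide, ic50 * factor, temperature, source, allele)
            )
        except DataError as exc:
            raise DataError(f"row {row_no}: {exc}") from exc
    return records


def filter_by_length(
    records: list[BindingRecord], length: int
) -> list[BindingRecord]:
    """Keep peptides matching the reference peptide length, in order."""
    if length <= 0:
        raise DataError("length must be positive")
    return [r for r in records if len(r.peptide_sequence) == length]


def resolve_duplicates(
    records: list[BindingRecord],
    policy: str = "exclude",
    fold_threshold: float = 10.0,
) -> list[BindingRecord]:
    """Reduce to at most one record per peptide sequence.

    ``exclude`` drops peptides whose replicate IC50 values span more than
    `fold_threshold` (irreconcilable measurements) and merges consistent
    replicates by geometric mean; ``geometric_mean`` always merges;
    ``keep_first`` keeps the first occurrence in file order.
    """
    if policy not in ("exclude", "geometric_mean", "keep_first"):
        raise DataError(f"unknown duplicate policy {policy!r}")
    by_peptide: dict[str, list[BindingRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.peptide_sequence not in by_peptide:
            order.append(r.peptide_sequence)
        by_peptide.setdefault(r.peptide_sequence, []).append(r)

    out: list[BindingRecord] = []
    for peptide in order:
        group = by_peptide[peptide]
        if len(group) == 1:
            out.append(group[0])
            continue
        if policy == "keep_first":
            out.append(group[0])
            continue
        values = [r.ic50 for r in group]
        if policy == "exclude" and max(values) / min(values) > fold_threshold:
            warnings.warn(
                f"peptide {peptide} excluded: replicate IC50 values span "
                f">{fold_threshold:g}-fold"
            )
            continue
        geo = math.exp(sum(math.log(v) for v in values) / len(values))
        first = group[0]
        out.append(make_record(
            peptide, geo, first.temperature, first.source_tag, first.allele
        ))
    return out


def records_to_frame(records: list[BindingRecord]) -> pd.DataFrame:
    """Tabular view with the derived dG column (kJ/mol)."""
    return pd.DataFrame({
        "peptide": [r.peptide_sequence for r in records],
        "ic50_M": [r.ic50 for r in records],
        "temperature_C": [r.temperature for r in records],
        "dG_bind_kJ_mol": [r.dg_bind for r in records],
        "source": [r.source_tag for r in records],
    })
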