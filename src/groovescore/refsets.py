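"""Reference-set experiments: how structure choice governs predictive power.

A reference set is a combination of crystal structures, one per distinct
native peptide.  For each set the native complexes are scored, calibrated
and cross-validated, and the resulting q2 / S_press are correlated (by
Spearman rank) against the structural spread of the set: the mean pairwise
RMSD over whole structures, MHC frames alone and peptides alone, plus the
mean crystallographic resolution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, StructureError
from .geometry import kabsch
from .regress import RegressionError, loocv
from .structio import ComplexStructure
from .terms import TermParams, DEFAULT_PARAMS, compute_terms

SELECTIONS = ("whole", "mhc", "peptide")


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of one structure onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_matched: int


@dataclass(frozen=True)
class ReferenceSet:
    """A combination of structures, at most one per native peptide."""

    members: tuple[tuple[str, str], ...]  # (pdb_id, native peptide)
    set_id: str

    def __post_init__(self):
        peptides = [p for _, p in self.members]
        if len(set(peptides)) != len(peptides):
            raise DataError(f"set {self.set_id}: duplicate native peptide")
        if len(self.members) < 2:
            raise DataError(f"set {self.set_id}: at least 2 members required")


def _matched_coords(
    a: ComplexStructure, b: ComplexStructure, selection: str
) -> tuple[np.ndarray, np.ndarray]:
    if selection not in SELECTIONS:
        raise DataError(f"unknown selection {selection!r}")

    def keys(c: ComplexStructure) -> dict:
        out = {}
        if selection in ("whole", "mhc"):
            chain_order = {
                ch: i for i, ch in enumerate(
                    sorted({atom.chain_id for atom in c.mhc_atoms})
                )
            }
            for atom in c.mhc_atoms:
                if not atom.is_hydrogen:
                    out[(
                        "m", chain_order[atom.chain_id], atom.residue_seq,
                        atom.insertion_code, atom.name,
                    )] = atom.coords
        if selection in ("whole", "peptide"):
            for pos, residue in enumerate(c.peptide_residues()):
                for atom in residue:
                    if not atom.is_hydrogen:
                        out[("p", pos, atom.name)] = atom.coords
        return out

    ka, kb = keys(a), keys(b)
    shared = sorted(set(ka) & set(kb), key=str)
    if len(shared) < 3:
        raise StructureError(
            f"only {len(shared)} matched atoms for selection {selection!r}"
        )
    return (
        np.array([ka[k] for k in shared]),
        np.array([kb[k] for k in shared]),
    )


def superpose(
    a: ComplexStructure, b: ComplexStructure, selection: str = "whole"
) -> SuperpositionResult:
    """Kabsch superposition of `b` onto `a` over matched heavy atoms.

    Atoms are matched by chain role, residue position and atom name.
    """
    target, mobile = _matched_coords(a, b, selection)
    R, t, rmsd = kabsch(target, mobile)
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms_matched=len(target)
    )


def mean_pairwise_rmsd(
    structures: list[ComplexStructure], selection: str = "whole"
) -> float:
    """Unweighted mean superposition RMSD over all unordered pairs."""
    if len(structures) < 2:
        raise DataError("at least 2 structures required")
    values = [
        superpose(a, b, selection).rmsd
        for a, b in itertools.combinations(structures, 2)
    ]
    return float(np.mean(values))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("spearman_rho needs two equal vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DataError("zero rank variance: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def enumerate_reference_sets(
    table: list[tuple[str, str]]
) -> list[ReferenceSet]:
    """All structure combinations using one structure per native peptide.

    `table` lists (pdb_id, peptide) rows.  Peptides represented by several
    structures contribute one chosen structure each (Cartesian product);
    peptides with a single structure are always included.  Output order is
    deterministic (lexicographic in the per-group choices).
    """
    if not table:
        raise DataError("empty structure table")
    groups: dict[str, list[str]] = {}
    for pdb_id, peptide in table:
        groups.setdefault(peptide, []).append(pdb_id)
    peptides = sorted(groups)
    multi = [p for p in peptides if len(groups[p]) > 1]
    singles = [(groups[p][0], p) for p in peptides if len(groups[p]) == 1]

    sets = []
    for combo in itertools.product(*(sorted(groups[p]) for p in multi)):
        members = tuple(sorted(
            list(zip(combo, multi)) + singles, key=lambda m: m[0]
        ))
        set_id = "+".join(pdb for pdb, _ in members)
        sets.append(ReferenceSet(members=members, set_id=set_id))
    return sets


def run_refset_experiment(
    sets: list[ReferenceSet],
    bindings: dict[str, float],
    structures: dict[str, ComplexStructure],
    mode: str = "native",
    params: TermParams = DEFAULT_PARAMS,
    records=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every reference set and correlate quality with similarity.

    `bindings` maps native peptide to experimental dG (kJ/mol);
    `structures` maps pdb_id to a prepared complex.  In the default
    ``native`` mode each training point is a member's native complex.  Mode
    ``threaded`` additionally threads every binding record (`records`, a
    list of BindingRecord) onto every length-compatible member frame and
    pools the rows (exploratory).

    Returns (per-set results, Spearman correlation table).
    """
    if mode not in ("native", "threaded"):
        raise DataError(f"unknown mode {mode!r}")
    rows = []
    for ref_set in sets:
        for pdb_id, peptide in ref_set.members:
            if pdb_id not in structures:
                raise DataError(f"missing structure for member {pdb_id}")
            if peptide not in bindings:
                raise DataError(f"missing binding record for {peptide}")

        X, y, ids = [], [], []
        for pdb_id, peptide in ref_set.members:
            tv = compute_terms(structures[pdb_id], params, complex_id=pdb_id)
            X.append(tv.as_array())
            y.append(bindings[peptide])
            ids.append(pdb_id)
        if mode == "threaded":
            from .modeller import thread_peptide
            from .structio import assign_atom_classes, place_polar_hydrogens

            for pdb_id, _ in ref_set.members:
                ref = structures[pdb_id]
                for rec in records or []:
                    if len(rec.peptide_sequence) != len(ref.peptide_sequence):
                        continue
                    model = thread_peptide(ref, rec.peptide_sequence)
                    model = assign_atom_classes(place_polar_hydrogens(model))
                    tv = compute_terms(model, params)
                    X.append(tv.as_array())
                    y.append(rec.dg_bind)
                    ids.append(f"{pdb_id}:{rec.peptide_sequence}")

        X = np.array(X)
        y = np.array(y)
        try:
            cv = loocv(X, y, ids=ids)
            q2, s_press = cv.q2, cv.s_press
        except RegressionError as exc:
            warnings.warn(f"set {ref_set.set_id}: q2 undefined ({exc})")
            q2, s_press = np.nan, np.nan

        members = [structures[pdb_id] for pdb_id, _ in ref_set.members]
        rmsds = {}
        for selection in SELECTIONS:
            try:
                rmsds[selection] = mean_pairwise_rmsd(members, selection)
            except (StructureError, DataError) as exc:
                warnings.warn(
                    f"set {ref_set.set_id}: {selection} RMSD skipped ({exc})"
                )
                rmsds[selection] = np.nan
        resolutions = [
            m.resolution for m in members if m.resolution is not None
        ]
        if len(resolutions) < len(members):
            warnings.warn(
                f"set {ref_set.set_id}: members without resolution dropped "
                "from the resolution average"
            )
        rows.append({
            "set_id": ref_set.set_id,
            "members": ",".join(pdb for pdb, _ in ref_set.members),
            "n": len(ref_set.members),
            "q2": q2,
            "s_press_kJ_mol": s_press,
            "rmsd_whole_A": rmsds["whole"],
            "rmsd_mhc_A": rmsds["mhc"],
            "rmsd_peptide_A": rmsds["peptide"],
            "mean_resolution_A": (
                float(np.mean(resolutions)) if resolutions else np.nan
            ),
        })

    results = pd.DataFrame(rows)
    correlations = correlate_quality(results)
    return results, correlations


def correlate_quality(results: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of q2 and S_press against set characteristics."""
    rows = []
    usable = results.dropna(subset=["q2"])
    for label, column in (
        ("RMSD", "rmsd_whole_A"),
        ("RMSD_MHC", "rmsd_mhc_A"),
        ("RMSD_peptide", "rmsd_peptide_A"),
        ("Average resolution", "mean_resolution_A"),
    ):
        sub = usable.dropna(subset=[column])
        try:
            rho_q2 = spearman_rho(sub[column], sub["q2"])
            rho_sp = spearman_rho(sub[column], sub["s_press_kJ_mol"])
        except DataError:
            rho_q2 = rho_sp = np.nan
        rows.append({"characteristic": label, "q2": rho_q2, "s_press": rho_sp})
    return pd.DataFrame(rows)


def q2_distribution(results: pd.DataFrame, thresholds=(0.283, 0.5)) -> dict:
    """Counts of sets exceeding q2 thresholds (distribution summary)."""
    out = {"n_sets": int(len(results))}
    for t in thresholds:
        out[f"q2_gt_{t:g}"] = int((results["q2"] > t).sum())
    return out
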