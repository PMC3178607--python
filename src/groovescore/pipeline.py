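"""Workflow orchestration: validate, train/predict and reference-set runs.

Each workflow is a pure function over in-memory objects plus a thin
file-based wrapper driven by a YAML config, so every stage stays
independently invocable and testable.  All free energies are kJ/mol and
every output table carries units in its column headers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .affinity import (
    BindingRecord, filter_by_length, load_binding_table, resolve_duplicates,
)
from .errors import DataError
from .modeller import thread_peptide
from .refsets import (
    enumerate_reference_sets, q2_distribution, run_refset_experiment,
)
from .regress import fit_pls, loocv
from .structio import (
    ComplexStructure, assign_atom_classes, place_polar_hydrogens,
    read_complex,
)
from .terms import DEFAULT_PARAMS, TermParams, compute_terms

logger = logging.getLogger("groovescore")

WORKFLOWS = ("validate", "train", "predict", "refsets", "fixtures")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    workflow: str
    structures: list = field(default_factory=list)  # dicts: path/pdb_id/chains
    binding_table: str | None = None
    binding_unit: str | None = None
    experimental_dg: str | None = None   # validate: TSV peptide/pdb_id/dG
    duplicate_policy: str = "exclude"
    n_components: int | None = None
    scale: bool = True
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("workflow") not in WORKFLOWS:
            raise DataError(
                f"workflow must be one of {WORKFLOWS}, got {raw.get('workflow')!r}"
            )
        return cls(**raw)


def prepare_complex(
    pdb_text: str, chain_roles: dict[str, str], pdb_id: str = ""
) -> ComplexStructure:
    """read -> place polar hydrogens -> assign atom classes."""
    c = read_complex(pdb_text, chain_roles, pdb_id)
    return assign_atom_classes(place_polar_hydrogens(c))


def prepare_threaded(
    reference: ComplexStructure, sequence: str
) -> ComplexStructure:
    """Thread, re-protonate and re-type one peptide model."""
    model = thread_peptide(reference, sequence)
    return assign_atom_classes(place_polar_hydrogens(model))


def _load_structures(cfg: RunConfig) -> dict[str, ComplexStructure]:
    out = {}
    for entry in cfg.structures:
        path = Path(entry["path"])
        pdb_id = entry.get("pdb_id", path.stem.upper())
        out[pdb_id] = prepare_complex(
            path.read_text(), entry["chains"], pdb_id
        )
    return out


# ---------------------------------------------------------------------------
# validate: native complexes with known experimental dG
# ---------------------------------------------------------------------------

def run_validate(
    complexes: list[ComplexStructure],
    dg_by_id: dict[str, float],
    params: TermParams = DEFAULT_PARAMS,
    n_components: int | None = None,
    scale: bool = True,
) -> dict:
    """Score native complexes and leave-one-out validate against known dG.

    Each training point is a peptide in its own crystal structure; the
    report lists per-peptide cross-validated predictions and deviations
    alongside q2 and S_press.
    """
    usable = [c for c in complexes if c.pdb_id in dg_by_id]
    if len(usable) < 4:
        raise DataError(
            f"validation requires at least 4 usable complexes, got {len(usable)}"
        )
    ids = [c.pdb_id for c in usable]
    X = np.array([
        compute_terms(c, params).as_array() for c in usable
    ])
    y = np.array([dg_by_id[c.pdb_id] for c in usable])
    cv = loocv(X, y, n_components=n_components, scale=scale, ids=ids)
    model = fit_pls(X, y, n_components=n_components, scale=scale, ids=ids)
    table = pd.DataFrame({
        "peptide": [c.peptide_sequence for c in usable],
        "pdb_id": ids,
        "dG_exp_kJ_mol": y,
        "dG_pred_cv_kJ_mol": [cv.per_fold_predictions[i] for i in ids],
    })
    table["deviation_kJ_mol"] = (
        table["dG_pred_cv_kJ_mol"] - table["dG_exp_kJ_mol"]
    )
    return {"table": table, "q2": cv.q2, "s_press": cv.s_press,
            "model": model, "cv": cv, "terms": X}


# ---------------------------------------------------------------------------
# train / predict: thread a binding table onto one reference frame
# ---------------------------------------------------------------------------

def run_train_predict(
    reference: ComplexStructure,
    records: list[BindingRecord],
    params: TermParams = DEFAULT_PARAMS,
    duplicate_policy: str = "exclude",
    n_components: int | None = None,
    scale: bool = True,
) -> dict:
    """Thread every peptide onto the reference, calibrate and cross-validate."""
    length = len(reference.peptide_sequence)
    kept = filter_by_length(records, length)
    dropped = len(records) - len(kept)
    if dropped:
        logger.info(
            "length filter: %d of %d peptides dropped (reference length %d)",
            dropped, len(records), length,
        )
    kept = resolve_duplicates(kept, policy=duplicate_policy)
    if not kept:
        raise DataError(
            "no peptides left after filtering: only peptides with the same "
            f"length as the reference peptide ({length}) are usable"
        )
    if len(kept) < 4:
        raise DataError(
            f"at least 4 peptides required for cross-validation, got {len(kept)}"
        )

    ids, X, y = [], [], []
    for rec in kept:
        model_structure = prepare_threaded(reference, rec.peptide_sequence)
        tv = compute_terms(model_structure, params,
                           complex_id=rec.peptide_sequence)
        ids.append(rec.peptide_sequence)
        X.append(tv.as_array())
        y.append(rec.dg_bind)
    X = np.array(X)
    y = np.array(y)
    cv = loocv(X, y, n_components=n_components, scale=scale, ids=ids)
    model = fit_pls(X, y, n_components=n_components, scale=scale, ids=ids)
    table = pd.DataFrame({
        "peptide": ids,
        "dG_exp_kJ_mol": y,
        "dG_pred_cv_kJ_mol": [cv.per_fold_predictions[i] for i in ids],
    })
    table["deviation_kJ_mol"] = (
        table["dG_pred_cv_kJ_mol"] - table["dG_exp_kJ_mol"]
    )
    return {"table": table, "q2": cv.q2, "s_press": cv.s_press,
            "model": model, "cv": cv, "terms": X}


# ---------------------------------------------------------------------------
# refsets: combinations of reference structures, native mode
# ---------------------------------------------------------------------------

def run_refsets(
    structure_table: list[tuple[str, str]],
    structures: dict[str, ComplexStructure],
    records: list[BindingRecord],
    params: TermParams = DEFAULT_PARAMS,
    mode: str = "native",
) -> dict:
    """Enumerate reference sets, score each, and correlate with similarity."""
    sets = enumerate_reference_sets(structure_table)
    bindings = {r.peptide_sequence: r.dg_bind for r in records}
    results, correlations = run_refset_experiment(
        sets, bindings, structures, mode=mode, params=params, records=records,
    )
    return {
        "results": results,
        "correlations": correlations,
        "distribution": q2_distribution(results),
    }


# ---------------------------------------------------------------------------
# config-file driver
# ---------------------------------------------------------------------------

def run_from_config(cfg: RunConfig) -> dict:
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structures = _load_structures(cfg)

    if cfg.workflow == "validate":
        if not cfg.experimental_dg:
            raise DataError("validate requires experimental_dg (TSV path)")
        dg_frame = pd.read_csv(cfg.experimental_dg, sep="\t")
        dg_by_id = dict(zip(dg_frame["pdb_id"], dg_frame["dg_exp_kJ_mol"]))
        report = run_validate(
            list(structures.values()), dg_by_id,
            n_components=cfg.n_components, scale=cfg.scale,
        )
        report["table"].to_csv(out_dir / "validation.tsv", sep="\t",
                               index=False)
        _write_model(report["model"], out_dir / "model.json")
        _write_cv_summary(report, out_dir / "cv.tsv")
        return report

    if cfg.workflow == "train":
        if not (cfg.binding_table and cfg.binding_unit):
            raise DataError("train requires binding_table and binding_unit")
        records = load_binding_table(
            Path(cfg.binding_table).read_text(), unit=cfg.binding_unit
        )
        reference = next(iter(structures.values()))
        report = run_train_predict(
            reference, records, duplicate_policy=cfg.duplicate_policy,
            n_components=cfg.n_components, scale=cfg.scale,
        )
        report["table"].to_csv(out_dir / "predictions.tsv", sep="\t",
                               index=False)
        _write_model(report["model"], out_dir / "model.json")
        _write_cv_summary(report, out_dir / "cv.tsv")
        return report

    if cfg.workflow == "refsets":
        if not (cfg.binding_table and cfg.binding_unit):
            raise DataError("refsets requires binding_table and binding_unit")
        records = load_binding_table(
            Path(cfg.binding_table).read_text(), unit=cfg.binding_unit
        )
        pairs = [
            (entry.get("pdb_id", Path(entry["path"]).stem.upper()),
             entry["peptide"])
            for entry in cfg.structures
        ]
        report = run_refsets(pairs, structures, records)
        report["results"].to_csv(out_dir / "refsets_q2.tsv", sep="\t",
                                 index=False)
        report["correlations"].to_csv(out_dir / "correlations.tsv", sep="\t",
                                      index=False)
        return report

    raise DataError(f"workflow {cfg.workflow!r} is not file-driven")


def _write_model(model, path: Path) -> None:
    path.write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def _write_cv_summary(report: dict, path: Path) -> None:
    pd.DataFrame([{
        "q2": report["q2"],
        "s_press_kJ_mol": report["s_press"],
        "n": report["cv"].n,
    }]).to_csv(path, sep="\t", index=False)
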