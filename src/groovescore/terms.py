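"""The five semi-empirical interaction terms for one MHC-peptide complex.

ChemScore-family functional forms: every pairwise contribution is a block
(ramp) function of a geometric deviation, equal to 1 inside an inner bound,
falling linearly to 0 at an outer bound.  HB scores intermolecular
donor-H...acceptor triples by distance and angle, LIPO scores lipophilic
contact pairs, BP penalises mixed polar/lipophilic contacts, ROT counts
frozen rotatable side-chain bonds of the peptide, and DESOLV estimates the
solvation change on binding from solvent-accessible surface areas (or from a
table of externally computed Poisson-Boltzmann energies).

All sums are restricted to MHC <-> peptide pairs; a pair search with an 8 A
cutoff (beyond the support of every kernel) keeps the cost linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _chemdata as chem
from .errors import DataError, ParameterError, StructureError
from .structio import Atom, ComplexStructure

TERM_NAMES = ("HB", "LIPO", "BP", "ROT", "DESOLV")

#: kJ/mol per A^2 of solvent-accessible area, by atom class (positive sigma:
#: solvating the atom is favourable, burying it costs energy).
DEFAULT_SIGMA = {
    chem.LIPOPHILIC: 0.067,
    chem.POLAR_NEUTRAL: 0.033,
    chem.DONOR: -0.025,
    chem.ACCEPTOR: -0.025,
    chem.DONOR_ACCEPTOR: -0.025,
    chem.OTHER: 0.0,
}


@dataclass(frozen=True)
class TermParams:
    """Kernel parameters; defaults are the ChemScore values (A, degrees)."""

    hb_d_ideal: float = 1.85
    hb_d_inner: float = 0.25
    hb_d_outer: float = 0.65
    hb_theta_inner: float = 30.0
    hb_theta_outer: float = 80.0
    lipo_pad: float = 0.5
    lipo_width: float = 3.0
    cutoff: float = 8.0
    probe_radius: float = 1.4
    sasa_points: float = 1000
    sigma: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    heavy_atom_hb: bool = False
    hb_da_ideal: float = 2.85


DEFAULT_PARAMS = TermParams()


@dataclass
class TermVector:
    """The five descriptors for one complex (HB, LIPO, BP dimensionless
    sums; ROT a count; DESOLV in kJ/mol)."""

    hb: float
    lipo: float
    bp: float
    rot: int
    desolv: float
    complex_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.hb, self.lipo, self.bp, self.rot, self.desolv], dtype=float
        )


def block(x: float, x1: float, x2: float) -> float:
    """Ramp weight: 1 for x <= x1, linear to 0 at x2, 0 beyond."""
    if x1 >= x2:
        raise ParameterError(f"block bounds must satisfy x1 < x2 ({x1}, {x2})")
    if x <= x1:
        return 1.0
    if x >= x2:
        return 0.0
    return (x2 - x) / (x2 - x1)


def _require_typed(atoms: list[Atom]) -> None:
    for a in atoms:
        if a.atom_class is None or a.vdw_radius is None:
            raise StructureError(
                f"atom {a.name} of {a.residue_name} {a.residue_seq} is "
                "untyped; run assign_atom_classes first"
            )


def _heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if not a.is_hydrogen]


def _donors_with_h(atoms: list[Atom]) -> list[tuple[Atom, list[Atom]]]:
    by_res: dict[tuple, list[Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_key, []).append(a)
    out = []
    for res_atoms in by_res.values():
        hydrogens = [a for a in res_atoms if a.is_hydrogen]
        for d in res_atoms:
            if d.atom_class in (chem.DONOR, chem.DONOR_ACCEPTOR):
                attached = [
                    h for h in hydrogens
                    if np.linalg.norm(h.coords - d.coords) < 1.3
                ]
                if attached:
                    out.append((d, attached))
    return out


def _acceptors(atoms: list[Atom]) -> list[Atom]:
    return [
        a for a in _heavy(atoms)
        if a.atom_class in (chem.ACCEPTOR, chem.DONOR_ACCEPTOR)
    ]


def hb_term(c: ComplexStructure, params: TermParams = DEFAULT_PARAMS) -> float:
    """Hydrogen-bond sum over intermolecular donor-H...acceptor triples."""
    _require_typed(c.all_atoms)
    total = 0.0
    for donor_side, acceptor_side in (
        (c.mhc_atoms, c.peptide_atoms),
        (c.peptide_atoms, c.mhc_atoms),
    ):
        acceptors = _acceptors(acceptor_side)
        if not acceptors:
            continue
        acc_coords = np.array([a.coords for a in acceptors])
        tree = cKDTree(acc_coords)
        if params.heavy_atom_hb:
            reach = params.hb_da_ideal + params.hb_d_outer
            donors = [
                d for d in _heavy(donor_side)
                if d.atom_class in (chem.DONOR, chem.DONOR_ACCEPTOR)
            ]
            for d in donors:
                for j in tree.query_ball_point(d.coords, reach):
                    dist = float(np.linalg.norm(acc_coords[j] - d.coords))
                    total += block(
                        abs(dist - params.hb_da_ideal),
                        params.hb_d_inner, params.hb_d_outer,
                    )
        else:
            reach = params.hb_d_ideal + params.hb_d_outer
            for d, hydrogens in _donors_with_h(donor_side):
                for h in hydrogens:
                    for j in tree.query_ball_point(h.coords, reach):
                        a = acceptors[j]
                        d_ha = float(np.linalg.norm(a.coords - h.coords))
                        v1 = d.coords - h.coords
                        v2 = a.coords - h.coords
                        cos_t = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        theta = np.degrees(np.arccos(np.clip(cos_t, -1, 1)))
                        total += (
                            block(abs(d_ha - params.hb_d_ideal),
                                  params.hb_d_inner, params.hb_d_outer)
                            * block(abs(theta - 180.0),
                                    params.hb_theta_inner,
                                    params.hb_theta_outer)
                        )
    return total


def _contact_sum(
    c: ComplexStructure,
    params: TermParams,
    pair_filter,
) -> float:
    mhc = _heavy(c.mhc_atoms)
    pep = _heavy(c.peptide_atoms)
    if not mhc or not pep:
        return 0.0
    mhc_coords = np.array([a.coords for a in mhc])
    pep_coords = np.array([a.coords for a in pep])
    pairs = cKDTree(mhc_coords).query_ball_tree(
        cKDTree(pep_coords), params.cutoff
    )
    total = 0.0
    for i, js in enumerate(pairs):
        for j in js:
            a, b = mhc[i], pep[j]
            if not pair_filter(a, b):
                continue
            r1 = a.vdw_radius + b.vdw_radius + params.lipo_pad
            d = float(np.linalg.norm(mhc_coords[i] - pep_coords[j]))
            total += block(d, r1, r1 + params.lipo_width)
    return total


def lipo_term(c: ComplexStructure, params: TermParams = DEFAULT_PARAMS) -> float:
    """Lipophilic contact sum over intermolecular lipophilic atom pairs."""
    _require_typed(c.all_atoms)
    return _contact_sum(
        c, params,
        lambda a, b: a.atom_class == chem.LIPOPHILIC
        and b.atom_class == chem.LIPOPHILIC,
    )


def bp_term(c: ComplexStructure, params: TermParams = DEFAULT_PARAMS) -> float:
    """Unfavourable polar/lipophilic contact sum (both directions)."""
    _require_typed(c.all_atoms)

    def mixed(a: Atom, b: Atom) -> bool:
        return (
            a.atom_class == chem.LIPOPHILIC and b.atom_class in chem.POLAR_CLASSES
        ) or (
            b.atom_class == chem.LIPOPHILIC and a.atom_class in chem.POLAR_CLASSES
        )

    return _contact_sum(c, params, mixed)


def rot_term(sequence: str) -> int:
    """Rotatable side-chain bonds frozen on binding; sequence-only."""
    total = 0
    for letter in sequence:
        if letter not in chem.ROTATABLE_BOND_COUNTS:
            raise DataError(f"unknown amino-acid letter {letter!r}")
        total += chem.ROTATABLE_BOND_COUNTS[letter]
    return total


def _solvation_energy(atoms: list[Atom], params: TermParams) -> float:
    import biotite.structure as struc

    heavy = _heavy(atoms)
    n = len(heavy)
    arr = struc.AtomArray(n)
    arr.coord[:] = np.array([a.coords for a in heavy])
    arr.element = np.array([a.element for a in heavy])
    arr.atom_name = np.array([a.name for a in heavy])
    arr.res_name = np.array([a.residue_name for a in heavy])
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.array([a.chain_id for a in heavy])
    areas = struc.sasa(
        arr,
        probe_radius=params.probe_radius,
        vdw_radii=np.array([a.vdw_radius for a in heavy]),
        point_number=int(params.sasa_points),
    ).astype(float)
    sigma = np.array([params.sigma.get(a.atom_class, 0.0) for a in heavy])
    return float(np.dot(sigma, areas))


def desolv_term(
    c: ComplexStructure,
    backend: str = "sasa",
    external_table: dict[str, float] | None = None,
    params: TermParams = DEFAULT_PARAMS,
    complex_id: str = "",
) -> float:
    """Desolvation free energy in kJ/mol.

    Default backend computes G_solv(complex) - G_solv(MHC) - G_solv(peptide)
    from per-class atomic solvation parameters times solvent-accessible
    areas (probe 1.4 A).  Backend ``external`` reads a per-complex value
    from a table of precomputed Poisson-Boltzmann energies.
    """
    if backend == "external":
        if external_table is None:
            raise DataError("external desolvation backend requires a table")
        key = complex_id or c.pdb_id
        if key not in external_table:
            raise DataError(f"no external desolvation value for {key!r}")
        return float(external_table[key])
    if backend != "sasa":
        raise ParameterError(f"unknown desolvation backend {backend!r}")
    _require_typed(c.all_atoms)
    g_complex = _solvation_energy(c.all_atoms, params)
    g_mhc = _solvation_energy(c.mhc_atoms, params)
    g_pep = _solvation_energy(c.peptide_atoms, params)
    return g_complex - g_mhc - g_pep


def compute_terms(
    c: ComplexStructure,
    params: TermParams = DEFAULT_PARAMS,
    complex_id: str = "",
    desolv_backend: str = "sasa",
    external_table: dict[str, float] | None = None,
) -> TermVector:
    """Assemble the five-term descriptor vector for a prepared complex."""
    return TermVector(
        hb=hb_term(c, params),
        lipo=lipo_term(c, params),
        bp=bp_term(c, params),
        rot=rot_term(c.peptide_sequence),
        desolv=desolv_term(
            c, desolv_backend, external_table, params,
            complex_id=complex_id or c.pdb_id,
        ),
        complex_id=complex_id or c.pdb_id,
    )
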