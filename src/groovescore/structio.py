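"""Reading, cleaning and atom-typing of MHC-peptide complexes.

A complex is a set of typed atoms split into an MHC frame (one or more
chains, e.g. heavy chain + beta-2-microglobulin for class I, alpha + beta
for class II) and a single bound peptide chain.  Chain roles are always
declared explicitly by the caller because chain naming in deposited
structures is inconsistent.  Waters, heteroatoms, T-cell receptors and any
other chain declared ``discarded`` are removed on ingestion; alternate
conformations are reduced to the highest-occupancy location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import _chemdata as chem
from .errors import StructureError

MHC = "mhc"
PEPTIDE = "peptide"
DISCARDED = "discarded"

_VALID_ROLES = {MHC, PEPTIDE, DISCARDED}


@dataclass
class Atom:
    """One atom with coordinates in Angstrom and ChemScore-style typing."""

    name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_seq: int
    chain_id: str
    insertion_code: str = ""
    atom_class: str | None = None
    vdw_radius: float | None = None
    partial_charge: float | None = None
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class ComplexStructure:
    """Typed atoms of one MHC molecule plus one bound peptide chain."""

    mhc_atoms: list[Atom]
    peptide_atoms: list[Atom]
    peptide_sequence: str
    pdb_id: str = ""
    resolution: float | None = None
    chain_roles: dict[str, str] = field(default_factory=dict)

    @property
    def all_atoms(self) -> list[Atom]:
        return self.mhc_atoms + self.peptide_atoms

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            [a.copy() for a in self.mhc_atoms],
            [a.copy() for a in self.peptide_atoms],
            self.peptide_sequence,
            self.pdb_id,
            self.resolution,
            dict(self.chain_roles),
        )

    def peptide_residues(self) -> list[list[Atom]]:
        """Peptide atoms grouped by residue, in residue-number order."""
        return _group_residues(self.peptide_atoms)

    def mhc_residues(self) -> list[list[Atom]]:
        return _group_residues(self.mhc_atoms)


def _group_residues(atoms: list[Atom]) -> list[list[Atom]]:
    groups: dict[tuple, list[Atom]] = {}
    for a in atoms:
        groups.setdefault(a.residue_key, []).append(a)
    return [
        groups[k]
        for k in sorted(groups, key=lambda k: (k[0], k[1], k[2]))
    ]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_complex(
    pdb_text: str,
    chain_roles: dict[str, str],
    pdb_id: str = "",
) -> ComplexStructure:
    """Parse PDB-format text into a cleaned :class:`ComplexStructure`.

    `chain_roles` maps chain id to ``mhc`` / ``peptide`` / ``discarded``.
    Waters, HETATM records, discarded and undeclared chains are dropped;
    for alternate locations the highest-occupancy altloc is kept (ties
    resolved in favour of altloc 'A').  Peptide residues must carry their
    full heavy side chain; missing MHC side-chain atoms are tolerated.
    """
    for ch, role in chain_roles.items():
        if role not in _VALID_ROLES:
            raise StructureError(f"unknown role {role!r} for chain {ch!r}")
    peptide_chains = [c for c, r in chain_roles.items() if r == PEPTIDE]
    if len(peptide_chains) != 1:
        raise StructureError(
            f"exactly one peptide chain required, got {peptide_chains!r}"
        )

    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise StructureError("no model in PDB input")
    model = structure[0]
    present = {chain.name for chain in model}
    for ch in chain_roles:
        if ch not in present:
            raise StructureError(f"declared chain {ch!r} not found in PDB input")

    resolution = structure.resolution if structure.resolution > 0 else None
    if not pdb_id:
        pdb_id = structure.name.strip()

    mhc_atoms: list[Atom] = []
    peptide_atoms: list[Atom] = []
    for chain in model:
        role = chain_roles.get(chain.name)
        if role is None:
            warnings.warn(f"chain {chain.name!r} not declared: discarded")
            continue
        if role == DISCARDED:
            continue
        target = mhc_atoms if role == MHC else peptide_atoms
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            atoms = _resolve_altlocs(res)
            names = {a.name for a in atoms if a.element.name != "H"}
            if not {"N", "CA", "C"} <= names:
                raise StructureError(
                    f"residue {res.name} {chain.name}{res.seqid.num} lacks "
                    "backbone N/CA/C"
                )
            for g_atom in atoms:
                elem = g_atom.element.name.upper()
                target.append(Atom(
                    name=g_atom.name,
                    element=elem,
                    coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    chain_id=chain.name,
                    vdw_radius=chem.vdw_radius(elem),
                    occupancy=round(float(g_atom.occ), 4),
                    altloc="",
                ))

    if not peptide_atoms:
        raise StructureError(
            f"peptide chain {peptide_chains[0]!r} contains no polymer atoms"
        )

    sequence = _derive_sequence(peptide_atoms)
    _check_peptide_completeness(peptide_atoms)
    return ComplexStructure(
        mhc_atoms, peptide_atoms, sequence, pdb_id, resolution,
        dict(chain_roles),
    )


def _resolve_altlocs(res) -> list:
    by_name: dict[str, list] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for name, candidates in by_name.items():
        if len(candidates) == 1:
            chosen.append(candidates[0])
        else:
            # highest occupancy wins; exact ties prefer altloc 'A'
            chosen.append(min(
                candidates,
                key=lambda a: (-round(a.occ, 6), (a.altloc or "~") != "A",
                               a.altloc or "~"),
            ))
    return chosen


def _derive_sequence(peptide_atoms: list[Atom]) -> str:
    letters = []
    for residue in _group_residues(peptide_atoms):
        name = residue[0].residue_name
        if name not in chem.AA3_TO_1:
            raise StructureError(f"non-standard peptide residue {name!r}")
        letters.append(chem.AA3_TO_1[name])
    return "".join(letters)


def _check_peptide_completeness(peptide_atoms: list[Atom]) -> None:
    for residue in _group_residues(peptide_atoms):
        name = residue[0].residue_name
        have = {a.name for a in residue}
        missing = [
            n for n in chem.sidechain_heavy_atoms(name) if n not in have
        ]
        if missing:
            raise StructureError(
                f"peptide residue {name} "
                f"{residue[0].chain_id}{residue[0].residue_seq} is missing "
                f"side-chain atoms {missing} (complete peptides are required "
                "for comparable term values)"
            )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pdb(c: ComplexStructure, remarks: list[str] | None = None) -> str:
    """Serialise to PDB-format text (ATOM/TER/END, wwPDB v3.3 columns)."""
    lines = []
    if remarks:
        for r in remarks:
            lines.append(f"REMARK   6 {r}"[:80])
    if c.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION.    {c.resolution:4.2f} ANGSTROMS."
        )
    serial = 0
    for chain_atoms in (c.mhc_atoms, c.peptide_atoms):
        last_chain = None
        for a in chain_atoms:
            if last_chain is not None and a.chain_id != last_chain:
                lines.append("TER")
            last_chain = a.chain_id
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{a.altloc or ' '}"
                f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_seq:4d}"
                f"{a.insertion_code or ' '}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
        if chain_atoms:
            lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Polar hydrogen placement
# ---------------------------------------------------------------------------

_N_H = 1.01   # amide N-H bond length, Angstrom
_O_H = 0.96   # hydroxyl O-H bond length, Angstrom


def place_polar_hydrogens(c: ComplexStructure) -> ComplexStructure:
    """Return a copy with hydrogens on every donor N/O of standard residues.

    Geometric placement at canonical bond lengths (N-H 1.01 A, O-H 0.96 A):
    amide H anti to the preceding carbonyl oxygen, sp2 hydrogens in the
    plane of their group, sp3 hydrogens staggered.  Heavy atoms are never
    moved and pre-existing hydrogens are left untouched.
    """
    out = c.copy()
    for atoms in (out.mhc_atoms, out.peptide_atoms):
        new_hydrogens: list[Atom] = []
        residues = _group_residues(atoms)
        prev_by_chain: dict[str, list[Atom]] = {}
        for residue in residues:
            chain = residue[0].chain_id
            prev = prev_by_chain.get(chain)
            prev_by_chain[chain] = residue
            if residue[0].residue_name not in chem.STANDARD_RESIDUES:
                warnings.warn(
                    f"non-standard residue {residue[0].residue_name}: "
                    "no hydrogens placed"
                )
                continue
            new_hydrogens.extend(_protonate_residue(residue, prev))
        atoms.extend(new_hydrogens)
    return out


def _get(residue: list[Atom], name: str) -> Atom | None:
    for a in residue:
        if a.name == name:
            return a
    return None


def _has_attached_h(residue: list[Atom], heavy: Atom) -> bool:
    return any(
        a.is_hydrogen and np.linalg.norm(a.coords - heavy.coords) < 1.3
        for a in residue
    )


def _mk_h(template: Atom, name: str, coords: np.ndarray) -> Atom:
    return Atom(
        name=name, element="H", coords=coords,
        residue_name=template.residue_name,
        residue_seq=template.residue_seq,
        chain_id=template.chain_id,
        insertion_code=template.insertion_code,
        atom_class=chem.HYDROGEN if template.atom_class else None,
        vdw_radius=chem.vdw_radius("H"),
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bisector_h(x: Atom, a: Atom, b: Atom, length: float, name: str):
    direction = -_unit(_unit(a.coords - x.coords) + _unit(b.coords - x.coords))
    return _mk_h(x, name, x.coords + length * direction)


def _sp2_pair(x: Atom, a: Atom, plane_ref: Atom, names: tuple[str, str]):
    """Two in-plane hydrogens at 120 deg from the x-a bond (amide/guanidinium)."""
    e1 = _unit(x.coords - a.coords)
    normal = np.cross(a.coords - x.coords, plane_ref.coords - x.coords)
    normal = _unit(normal)
    out = []
    for name, sign in zip(names, (1.0, -1.0)):
        # rotate e1 by +-60 deg about the plane normal: H-X-A angle = 120 deg
        d = e1 * np.cos(np.deg2rad(60)) + sign * np.cross(normal, e1) * np.sin(
            np.deg2rad(60)
        )
        out.append(_mk_h(x, name, x.coords + _N_H * _unit(d)))
    return out


def _sp3_hydrogens(x: Atom, a: Atom, ref: Atom, n: int, length: float,
                   names: list[str]):
    """n staggered hydrogens about the a-x bond (dihedral 60/180/300 vs ref)."""
    out = []
    for name, dihedral in zip(names, (60.0, 180.0, 300.0)[:n]):
        pos = chem.place_from_internal(
            ref.coords, a.coords, x.coords, length, 109.5, dihedral
        )
        out.append(_mk_h(x, name, pos))
    return out


def _protonate_residue(residue: list[Atom], prev: list[Atom] | None):
    res_name = residue[0].residue_name
    added: list[Atom] = []

    n = _get(residue, "N")
    ca = _get(residue, "CA")
    c_at = _get(residue, "C")
    if res_name != "PRO" and n is not None and not _has_attached_h(residue, n):
        prev_c = _get(prev, "C") if prev else None
        if (
            prev_c is not None
            and prev_c.chain_id == n.chain_id
            and np.linalg.norm(prev_c.coords - n.coords) < 2.0
        ):
            added.append(_bisector_h(n, prev_c, ca, _N_H, "H"))
        elif ca is not None and c_at is not None:
            # chain-terminal amine: three staggered hydrogens
            added.extend(
                _sp3_hydrogens(n, ca, c_at, 3, _N_H, ["H1", "H2", "H3"])
            )

    def need(atom_name: str):
        a = _get(residue, atom_name)
        if a is None or _has_attached_h(residue, a):
            return None
        return a

    if res_name == "LYS" and (nz := need("NZ")):
        ce, cd = _get(residue, "CE"), _get(residue, "CD")
        if ce is not None and cd is not None:
            added.extend(
                _sp3_hydrogens(nz, ce, cd, 3, _N_H, ["HZ1", "HZ2", "HZ3"])
            )
    elif res_name == "ARG":
        if (ne := need("NE")):
            cd, cz = _get(residue, "CD"), _get(residue, "CZ")
            if cd is not None and cz is not None:
                added.append(_bisector_h(ne, cd, cz, _N_H, "HE"))
        for nh_name, h_names in (("NH1", ("HH11", "HH12")),
                                 ("NH2", ("HH21", "HH22"))):
            if (nh := need(nh_name)):
                cz, ne = _get(residue, "CZ"), _get(residue, "NE")
                if cz is not None and ne is not None:
                    added.extend(_sp2_pair(nh, cz, ne, h_names))
    elif res_name == "ASN" and (nd2 := need("ND2")):
        cg, od1 = _get(residue, "CG"), _get(residue, "OD1")
        if cg is not None and od1 is not None:
            added.extend(_sp2_pair(nd2, cg, od1, ("HD21", "HD22")))
    elif res_name == "GLN" and (ne2 := need("NE2")):
        cd, oe1 = _get(residue, "CD"), _get(residue, "OE1")
        if cd is not None and oe1 is not None:
            added.extend(_sp2_pair(ne2, cd, oe1, ("HE21", "HE22")))
    elif res_name == "HIS" and (ne2 := need("NE2")):
        cd2, ce1 = _get(residue, "CD2"), _get(residue, "CE1")
        if cd2 is not None and ce1 is not None:
            added.append(_bisector_h(ne2, cd2, ce1, _N_H, "HE2"))
    elif res_name == "TRP" and (ne1 := need("NE1")):
        cd1, ce2 = _get(residue, "CD1"), _get(residue, "CE2")
        if cd1 is not None and ce2 is not None:
            added.append(_bisector_h(ne1, cd1, ce2, _N_H, "HE1"))
    elif res_name == "SER" and (og := need("OG")):
        cb, ca2 = _get(residue, "CB"), _get(residue, "CA")
        if cb is not None and ca2 is not None:
            added.extend(_sp3_hydrogens(og, cb, ca2, 1, _O_H, ["HG"]))
    elif res_name == "THR" and (og1 := need("OG1")):
        cb, ca2 = _get(residue, "CB"), _get(residue, "CA")
        if cb is not None and ca2 is not None:
            added.extend(_sp3_hydrogens(og1, cb, ca2, 1, _O_H, ["HG1"]))
    elif res_name == "TYR" and (oh := need("OH")):
        cz, ce1 = _get(residue, "CZ"), _get(residue, "CE1")
        if cz is not None and ce1 is not None:
            pos = chem.place_from_internal(
                ce1.coords, cz.coords, oh.coords, _O_H, 110.0, 0.0
            )
            added.append(_mk_h(oh, "HH", pos))
    return added


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def assign_atom_classes(c: ComplexStructure) -> ComplexStructure:
    """Return a copy with `atom_class` (and vdW radius) set on every atom.

    Classification is a pure function of residue and atom name following the
    ChemScore-family convention: carbons/sulfurs bound only to C/S/H are
    lipophilic, N/O with model hydrogens are donors, bare O (and bare N) are
    acceptors, hydroxyl oxygens and the histidine ring nitrogens accept and
    donate, everything else is polar-neutral.
    """
    out = c.copy()
    for a in out.mhc_atoms + out.peptide_atoms:
        a.atom_class = chem.atom_class(a.residue_name, a.name, a.element)
        if a.vdw_radius is None:
            a.vdw_radius = chem.vdw_radius(a.element)
    return out
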