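"""Residue-level chemistry tables shared across the package.

Covalent topology and ideal coordinates for the 20 standard amino acids come
from the Chemical Component Dictionary bundled with biotite; on top of that
this module fixes the protonation model (which N/O carry polar hydrogens),
the ChemScore-style atom typing, PARSE-like van der Waals radii, side-chain
chi-angle definitions, and the per-residue rotatable-bond counts used by the
ROT term.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

# Atom classes
LIPOPHILIC = "lipophilic"
DONOR = "donor"
ACCEPTOR = "acceptor"
DONOR_ACCEPTOR = "donor_acceptor"
POLAR_NEUTRAL = "polar_neutral"
HYDROGEN = "hydrogen"
OTHER = "other"

POLAR_CLASSES = frozenset({DONOR, ACCEPTOR, DONOR_ACCEPTOR})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_RESIDUES = frozenset(AA3_TO_1)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain rotatable-bond counts for the ROT term (proline's ring bonds do
# not freeze on binding and count 0).
ROTATABLE_BOND_COUNTS = {
    "A": 0, "G": 0, "P": 0,
    "S": 1, "C": 1, "T": 1, "V": 1,
    "D": 2, "N": 2, "I": 2, "L": 2, "F": 2, "W": 2, "H": 2, "Y": 2,
    "E": 3, "Q": 3, "M": 3,
    "K": 4, "R": 4,
}

# PARSE-like van der Waals radii (Angstrom), keyed by element.
ELEMENT_VDW = {"C": 1.70, "N": 1.50, "O": 1.40, "S": 1.85, "H": 1.00}
DEFAULT_VDW = 1.70

# PARSE-like backbone partial charges (e); side-chain atoms default to 0 and
# users running an external Poisson-Boltzmann solver supply their own files.
BACKBONE_CHARGES = {"N": -0.40, "H": 0.40, "C": 0.55, "O": -0.55}

# Protonation model: side-chain N/O that carry hydrogens, with their count.
# Histidine is fixed to the NE2 tautomer.
SIDECHAIN_DONOR_H = {
    ("ARG", "NE"): 1, ("ARG", "NH1"): 2, ("ARG", "NH2"): 2,
    ("LYS", "NZ"): 3,
    ("ASN", "ND2"): 2, ("GLN", "NE2"): 2,
    ("HIS", "NE2"): 1,
    ("TRP", "NE1"): 1,
    ("SER", "OG"): 1, ("THR", "OG1"): 1, ("TYR", "OH"): 1,
}

HYDROXYL_OXYGENS = frozenset({("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")})
HIS_RING_NITROGENS = frozenset({("HIS", "ND1"), ("HIS", "NE2")})

# Standard chi-angle atom quadruples.  Proline's ring is threaded rigidly and
# is deliberately absent.
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [], "PRO": [],
}


@functools.lru_cache(maxsize=None)
def residue_template(res_name: str):
    """Idealised residue as a biotite AtomArray (with bonds), from the CCD."""
    import biotite.structure.info as info

    return info.residue(res_name)


@functools.lru_cache(maxsize=None)
def _template_index(res_name: str):
    tpl = residue_template(res_name)
    names = list(tpl.atom_name)
    elements = list(tpl.element)
    adjacency: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in tpl.bonds.as_array():
        adjacency[names[i]].add(names[j])
        adjacency[names[j]].add(names[i])
    return names, elements, adjacency


def template_element(res_name: str, atom_name: str) -> str | None:
    names, elements, _ = _template_index(res_name)
    try:
        return elements[names.index(atom_name)]
    except ValueError:
        return None


def heavy_neighbors(res_name: str, atom_name: str) -> tuple[str, ...]:
    """Heavy atoms covalently bound to `atom_name` within the residue."""
    names, elements, adjacency = _template_index(res_name)
    elem = dict(zip(names, elements))
    return tuple(n for n in adjacency.get(atom_name, ()) if elem[n] != "H")


@functools.lru_cache(maxsize=None)
def sidechain_heavy_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy side-chain atom names (template order), CB included."""
    names, elements, _ = _template_index(res_name)
    skip = set(BACKBONE_ATOMS) | {"OXT"}
    return tuple(
        n for n, e in zip(names, elements) if e != "H" and n not in skip
    )


@functools.lru_cache(maxsize=None)
def graph_distances(res_name: str) -> dict[tuple[str, str], int]:
    """All-pairs bond-graph distances (capped at 3) between heavy atoms."""
    names, elements, adjacency = _template_index(res_name)
    heavy = [n for n, e in zip(names, elements) if e != "H"]
    dist: dict[tuple[str, str], int] = {}
    for start in heavy:
        seen = {start: 0}
        frontier = [start]
        for d in (1, 2, 3):
            nxt = []
            for a in frontier:
                for b in adjacency[a]:
                    if b not in seen:
                        seen[b] = d
                        nxt.append(b)
            frontier = nxt
        for other, d in seen.items():
            dist[(start, other)] = d
    return dist


def n_hydrogens_in_model(res_name: str, atom_name: str) -> int:
    """Hydrogens an N/O carries under this package's protonation model."""
    if atom_name == "N" and res_name != "PRO":
        return 1  # chain-internal amide; termini handled geometrically
    return SIDECHAIN_DONOR_H.get((res_name, atom_name), 0)


@functools.lru_cache(maxsize=None)
def _class_table(res_name: str) -> dict[str, str]:
    names, elements, _ = _template_index(res_name)
    table = {}
    for name, elem in zip(names, elements):
        if elem == "H":
            table[name] = HYDROGEN
        elif elem in ("C", "S"):
            nbr_elems = {
                template_element(res_name, n)
                for n in heavy_neighbors(res_name, name)
            }
            table[name] = (
                LIPOPHILIC if nbr_elems <= {"C", "S"} else POLAR_NEUTRAL
            )
        elif elem == "O":
            if (res_name, name) in HYDROXYL_OXYGENS:
                table[name] = DONOR_ACCEPTOR
            else:
                table[name] = ACCEPTOR
        elif elem == "N":
            if (res_name, name) in HIS_RING_NITROGENS:
                table[name] = DONOR_ACCEPTOR
            elif n_hydrogens_in_model(res_name, name) > 0:
                table[name] = DONOR
            else:
                table[name] = ACCEPTOR
        else:
            table[name] = POLAR_NEUTRAL
    return table


def atom_class(res_name: str, atom_name: str, element: str = "") -> str:
    """ChemScore-style class for one atom; pure in (residue, atom name)."""
    if element == "H" or atom_name.startswith("H"):
        return HYDROGEN
    if res_name not in STANDARD_RESIDUES:
        warnings.warn(
            f"unknown residue {res_name!r}: atom {atom_name} classed 'other'"
        )
        return OTHER
    table = _class_table(res_name)
    if atom_name in table:
        return table[atom_name]
    if atom_name == "OXT":
        return ACCEPTOR
    warnings.warn(
        f"unknown atom {atom_name!r} in {res_name}: classed 'other'"
    )
    return OTHER


def vdw_radius(element: str) -> float:
    return ELEMENT_VDW.get(element.upper(), DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Internal-coordinate helpers (NeRF-style placement)
# ---------------------------------------------------------------------------

def place_from_internal(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position x with |x-c|=length, angle(x,c,b)=angle, dihedral(x,c,b,a)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        # collinear reference atoms: dihedral origin is arbitrary
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, bc)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(probe, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d = np.array([
        -length * np.cos(angle),
        -length * np.sin(angle) * np.cos(dihedral),
        -length * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, IUPAC convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))
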