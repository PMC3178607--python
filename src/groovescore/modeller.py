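"""Threading a peptide sequence onto the backbone of a reference complex.

The reference peptide's backbone atoms are kept exactly; positions whose
residue is unchanged keep their native side chain, mutated positions get a
side chain rebuilt from an ideal-geometry template.  The built-in side-chain
engine is deliberately simple and deterministic: canonical rotamers at
{-60, 60, 180} degrees per rotatable chi, placed greedily from the N- to
the C-terminus, choosing the rotamer with the fewest steric clashes against
the MHC frame and the already-placed peptide (ties broken by the lower
signed chi sum, then enumeration order).  Externally rebuilt peptides (e.g.
SCWRL output) can be substituted by reading the pre-threaded PDB file with
:func:`groovescore.structio.read_complex`.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _chemdata as chem
from .errors import ThreadingError
from .geometry import kabsch, rotate_about_axis
from .structio import Atom, ComplexStructure

CHI_SET = (-60.0, 60.0, 180.0)

_BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT")
_CLASH_FACTOR = 0.8


@dataclass
class RotamerChoice:
    """Chosen side-chain conformation at one peptide position."""

    residue_index: int
    chi_angles: tuple[float, ...]
    clash_count: int


@functools.lru_cache(maxsize=None)
def _chi_machinery(res_name: str):
    """Template coords, chi atom quadruples and downstream atom sets."""
    tpl = chem.residue_template(res_name)
    heavy = {
        n: tpl.coord[i].astype(float)
        for i, (n, e) in enumerate(zip(tpl.atom_name, tpl.element))
        if e != "H"
    }
    adjacency: dict[str, set[str]] = {n: set() for n in heavy}
    names = list(tpl.atom_name)
    elem = dict(zip(tpl.atom_name, tpl.element))
    for i, j, _ in tpl.bonds.as_array():
        a, b = names[i], names[j]
        if elem[a] != "H" and elem[b] != "H":
            adjacency[a].add(b)
            adjacency[b].add(a)
    downstream = []
    for a1, a2, a3, a4 in chem.CHI_ATOMS.get(res_name, []):
        seen = {a2, a3}
        frontier = [a3]
        while frontier:
            nxt = []
            for x in frontier:
                for y in adjacency[x]:
                    if y not in seen:
                        seen.add(y)
                        nxt.append(y)
            frontier = nxt
        moved = tuple(sorted(seen - {a2, a3}))
        downstream.append(((a1, a2, a3, a4), moved))
    return heavy, downstream


def _sidechain_candidates(
    res_name: str,
    backbone: dict[str, np.ndarray],
    chi_set: tuple[float, ...],
):
    """Yield (chi_combo, {atom_name: coords}) for every canonical rotamer."""
    template, chi_info = _chi_machinery(res_name)
    sc_names = chem.sidechain_heavy_atoms(res_name)
    if not sc_names:
        yield (), {}
        return
    tpl_bb = np.array([template[n] for n in ("N", "CA", "C")])
    native_bb = np.array([backbone[n] for n in ("N", "CA", "C")])
    R, t, _ = kabsch(native_bb, tpl_bb)
    placed = {n: R @ template[n] + t for n in sc_names}
    full = dict(placed)
    full.update({n: backbone[n] for n in ("N", "CA", "C")})

    if not chi_info or res_name == "PRO":
        # rigid side chain (ALA ring-free or proline ring)
        yield (), placed
        return

    n_chi = len(chi_info)
    for combo in itertools.product(chi_set, repeat=n_chi):
        coords = dict(full)
        for ((a1, a2, a3, a4), moved), chi in zip(chi_info, combo):
            current = chem.dihedral_angle(
                coords[a1], coords[a2], coords[a3], coords[a4]
            )
            delta = chi - current
            axis = coords[a3] - coords[a2]
            pts = np.array([coords[m] for m in moved])
            rotated = rotate_about_axis(pts, coords[a3], axis, delta)
            for m, p in zip(moved, rotated):
                coords[m] = p
        yield combo, {n: coords[n] for n in sc_names}


def _clash_score(
    sc_coords: dict[str, np.ndarray],
    res_name: str,
    backbone: dict[str, np.ndarray],
    env_tree: cKDTree | None,
    env_radii: np.ndarray,
    env_tags: np.ndarray,
    own_tag: int,
) -> int:
    """Clashing non-bonded pairs for one candidate side chain."""
    dist_table = chem.graph_distances(res_name)
    count = 0
    for name, xyz in sc_coords.items():
        r_s = chem.vdw_radius(chem.template_element(res_name, name) or "C")
        # environment (MHC + already-placed peptide atoms); the residue's
        # own backbone is handled below with 1-2/1-3 exclusions
        if env_tree is not None:
            for j in env_tree.query_ball_point(xyz, 3.0):
                if env_tags[j] == own_tag:
                    continue
                r_o = env_radii[j]
                if np.linalg.norm(xyz - env_tree.data[j]) < _CLASH_FACTOR * (
                    r_s + r_o
                ):
                    count += 1
        # own backbone beyond 1-2/1-3
        for bb_name, bb_xyz in backbone.items():
            if dist_table.get((name, bb_name), 4) <= 2:
                continue
            r_o = chem.vdw_radius(
                chem.template_element(res_name, bb_name) or "C"
            )
            if np.linalg.norm(xyz - bb_xyz) < _CLASH_FACTOR * (r_s + r_o):
                count += 1
    return count


def thread_peptide(
    reference: ComplexStructure,
    sequence: str,
    chi_set: tuple[float, ...] = CHI_SET,
    keep_identical: bool = True,
    return_details: bool = False,
):
    """Thread `sequence` onto the reference peptide backbone.

    Backbone atoms coincide exactly with the reference; the MHC frame is
    untouched.  Returns the threaded :class:`ComplexStructure` (heavy atoms
    only; re-protonate and re-type afterwards), or a
    ``(structure, [RotamerChoice])`` pair with `return_details`.
    """
    ref_residues = reference.peptide_residues()
    if len(sequence) != len(ref_residues):
        raise ThreadingError(
            f"peptide length {len(sequence)} does not match the reference "
            f"peptide length {len(ref_residues)}; only peptides matching the "
            "reference crystal structure's peptide length can be threaded"
        )
    bad = [x for x in sequence if x not in chem.AA1_TO_3]
    if bad:
        raise ThreadingError(f"unknown amino-acid letters {bad!r}")

    mhc_atoms = [a.copy() for a in reference.mhc_atoms]
    env_coords = [a.coords for a in mhc_atoms if not a.is_hydrogen]
    env_radii = [
        a.vdw_radius or chem.vdw_radius(a.element)
        for a in mhc_atoms
        if not a.is_hydrogen
    ]
    env_tags = [-1] * len(env_coords)

    # backbones first: they are fixed and visible to every rotamer choice
    backbones: list[dict[str, np.ndarray]] = []
    new_atoms_per_res: list[list[Atom]] = []
    for i, residue in enumerate(ref_residues):
        target3 = chem.AA1_TO_3[sequence[i]]
        bb = {}
        res_atoms = []
        for a in residue:
            if a.name in _BACKBONE_KEEP and not a.is_hydrogen:
                new = a.copy()
                new.residue_name = target3
                new.atom_class = None
                res_atoms.append(new)
                bb[a.name] = new.coords
        for required in ("N", "CA", "C"):
            if required not in bb:
                raise ThreadingError(
                    f"reference peptide residue {i} lacks backbone {required}"
                )
        backbones.append(bb)
        new_atoms_per_res.append(res_atoms)
        for a in res_atoms:
            env_coords.append(a.coords)
            env_radii.append(a.vdw_radius or chem.vdw_radius(a.element))
            env_tags.append(i)

    choices: list[RotamerChoice] = []
    for i, residue in enumerate(ref_residues):
        target = sequence[i]
        target3 = chem.AA1_TO_3[target]
        native = chem.AA3_TO_1[residue[0].residue_name]
        template_res = new_atoms_per_res[i][0]

        if native == target and keep_identical:
            side = [
                a.copy() for a in residue
                if a.name not in _BACKBONE_KEEP and not a.is_hydrogen
            ]
            chis = ()
            clashes = 0
        else:
            env_tree = cKDTree(np.array(env_coords))
            radii_arr = np.array(env_radii)
            tags_arr = np.array(env_tags)
            best = None
            for order, (combo, sc_coords) in enumerate(
                _sidechain_candidates(target3, backbones[i], chi_set)
            ):
                score = _clash_score(
                    sc_coords, target3, backbones[i], env_tree, radii_arr,
                    tags_arr, i,
                )
                key = (score, sum(combo), order)
                if best is None or key < best[0]:
                    best = (key, combo, sc_coords)
            (clashes, _, _), chis, sc_coords = best
            side = [
                Atom(
                    name=n,
                    element=chem.template_element(target3, n) or "C",
                    coords=xyz,
                    residue_name=target3,
                    residue_seq=template_res.residue_seq,
                    chain_id=template_res.chain_id,
                    insertion_code=template_res.insertion_code,
                    vdw_radius=chem.vdw_radius(
                        chem.template_element(target3, n) or "C"
                    ),
                )
                for n, xyz in sc_coords.items()
            ]
        for a in side:
            env_coords.append(a.coords)
            env_radii.append(a.vdw_radius or chem.vdw_radius(a.element))
            env_tags.append(i)
        new_atoms_per_res[i].extend(side)
        choices.append(RotamerChoice(i, tuple(chis), clashes))

    peptide_atoms = [a for res in new_atoms_per_res for a in res]
    threaded = ComplexStructure(
        mhc_atoms=mhc_atoms,
        peptide_atoms=peptide_atoms,
        peptide_sequence=sequence,
        pdb_id=reference.pdb_id,
        resolution=reference.resolution,
        chain_roles=dict(reference.chain_roles),
    )
    if return_details:
        return threaded, choices
    return threaded


def clash_count(c: ComplexStructure) -> int:
    """Non-bonded heavy-atom clashes of peptide side chains.

    Counts pairs (peptide side-chain atom, any other heavy atom) closer
    than 0.8 x the sum of their vdW radii, excluding 1-2/1-3 neighbours
    within the same residue; each qualifying pair is counted once.
    """
    residues = c.peptide_residues()
    side: list[tuple[Atom, int]] = []
    for idx, residue in enumerate(residues):
        sc_names = set(chem.sidechain_heavy_atoms(residue[0].residue_name))
        for a in residue:
            if a.name in sc_names and not a.is_hydrogen:
                side.append((a, idx))
    others = [a for a in c.all_atoms if not a.is_hydrogen]
    if not side or not others:
        return 0
    other_coords = np.array([a.coords for a in others])
    tree = cKDTree(other_coords)
    side_ids = {id(a) for a, _ in side}
    order = {id(a): k for k, (a, _) in enumerate(side)}
    count = 0
    for k, (s, res_idx) in enumerate(side):
        r_s = s.vdw_radius or chem.vdw_radius(s.element)
        dist_table = chem.graph_distances(s.residue_name)
        for j in tree.query_ball_point(s.coords, 3.0):
            o = others[j]
            if o is s:
                continue
            if id(o) in side_ids and order[id(o)] <= k:
                continue  # avoid double-counting side-chain/side-chain pairs
            if o.residue_key == s.residue_key:
                if dist_table.get((s.name, o.name), 4) <= 2:
                    continue
            r_o = o.vdw_radius or chem.vdw_radius(o.element)
            if np.linalg.norm(s.coords - o.coords) < _CLASH_FACTOR * (r_s + r_o):
                count += 1
    return count
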