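"""Shared fixtures: hand-built micro-structures and synthetic suites."""

from __future__ import annotations

import numpy as np
import pytest

from groovescore import _chemdata as chem
from groovescore.structio import Atom, ComplexStructure
from groovescore.synthgen import FixtureSpec, toy_complex_structure
from groovescore.terms import compute_terms

TRUE_COEF = np.array([-2.5, -0.15, 0.3, 1.2, 0.05])
TRUE_INTERCEPT = -10.0


def build_atom(
    name, element, xyz, res="ALA", seq=1, chain="A",
    atom_class=None, radius=None,
):
    """Minimal typed atom for kernel-level tests."""
    return Atom(
        name=name, element=element, coords=np.asarray(xyz, dtype=float),
        residue_name=res, residue_seq=seq, chain_id=chain,
        atom_class=atom_class,
        vdw_radius=radius if radius is not None else chem.vdw_radius(element),
    )


def bare_complex(mhc_atoms, pep_atoms, sequence="A"):
    return ComplexStructure(
        mhc_atoms=mhc_atoms, peptide_atoms=pep_atoms,
        peptide_sequence=sequence,
        chain_roles={"A": "mhc", "C": "peptide"},
    )


def ideal_gly_dipeptide():
    """Planar trans GLY-GLY backbone built from internal coordinates."""
    N1 = np.array([0.0, 0.0, 0.0])
    CA1 = np.array([1.46, 0.0, 0.0])
    C1 = chem.place_from_internal(np.array([0, 1, 0.0]), N1, CA1, 1.52, 111, 150)
    O1 = chem.place_from_internal(N1, CA1, C1, 1.23, 120.5, 0)
    N2 = chem.place_from_internal(N1, CA1, C1, 1.33, 116, 180)
    CA2 = chem.place_from_internal(CA1, C1, N2, 1.46, 122, 180)
    C2 = chem.place_from_internal(C1, N2, CA2, 1.52, 111, -60)
    O2 = chem.place_from_internal(N2, CA2, C2, 1.23, 120.5, 0)
    coords = {
        1: {"N": N1, "CA": CA1, "C": C1, "O": O1},
        2: {"N": N2, "CA": CA2, "C": C2, "O": O2},
    }
    atoms = [
        build_atom(n, n[0], coords[seq][n], res="GLY", seq=seq, chain="C")
        for seq in (1, 2)
        for n in ("N", "CA", "C", "O")
    ]
    return atoms, coords


@pytest.fixture
def gly_dipeptide_complex():
    pep, coords = ideal_gly_dipeptide()
    mhc = [
        build_atom(n, n[0], [x, 50.0, 0.0], res="GLY", seq=1, chain="A")
        for n, x in (("N", 0.0), ("CA", 1.46), ("C", 2.0), ("O", 1.3))
    ]
    return bare_complex(mhc, pep, "GG"), coords


def linear_validation_suite(seed=1, n=5):
    """Toy complexes differing only in H-bond geometry, with free energies
    exactly linear in their computed terms (identifiable per LOO fold)."""
    rng = np.random.default_rng(seed)
    complexes = []
    for k in range(n):
        spec = FixtureSpec(
            hbond_geometries=(
                (float(rng.uniform(1.7, 2.4)), float(rng.uniform(140, 180))),
            ),
            lipo_distances=(4.2,),
            bp_distances=(3.8,),
            extra_residues="K",
            seed=k,
        )
        c, _ = toy_complex_structure(spec)
        c.pdb_id = f"SYN{k}"
        complexes.append(c)
    dg = {
        c.pdb_id: float(
            TRUE_INTERCEPT + compute_terms(c).as_array() @ TRUE_COEF
        )
        for c in complexes
    }
    return complexes, dg


@pytest.fixture(scope="session")
def validation_suite():
    return linear_validation_suite()


@pytest.fixture(scope="session")
def mixed_fixture_complex():
    spec = FixtureSpec(
        hbond_geometries=((1.85, 180.0), (2.1, 155.0)),
        lipo_distances=(3.9, 5.2),
        bp_distances=(3.6, 6.0),
        extra_residues="KL",
        seed=11,
    )
    return toy_complex_structure(spec)
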