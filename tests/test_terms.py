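"""Scoring-term kernels against exhaustive-loop and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from groovescore import _chemdata as chem
from groovescore.errors import DataError, ParameterError, StructureError
from groovescore.terms import (
    DEFAULT_PARAMS, DEFAULT_SIGMA, TermParams, block, bp_term, compute_terms,
    desolv_term, hb_term, lipo_term, rot_term,
)
from groovescore.synthgen import FixtureSpec, toy_complex_structure

from conftest import bare_complex, build_atom


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no neighbour search)
# ---------------------------------------------------------------------------

def oracle_block(x, x1, x2):
    if x <= x1:
        return 1.0
    if x >= x2:
        return 0.0
    return (x2 - x) / (x2 - x1)


def oracle_hb(c, p=DEFAULT_PARAMS):
    total = 0.0
    for donor_side, acc_side in ((c.mhc_atoms, c.peptide_atoms),
                                 (c.peptide_atoms, c.mhc_atoms)):
        donors = [a for a in donor_side
                  if a.atom_class in ("donor", "donor_acceptor")]
        hydrogens = [a for a in donor_side if a.element == "H"]
        acceptors = [a for a in acc_side if a.element != "H"
                     and a.atom_class in ("acceptor", "donor_acceptor")]
        for d in donors:
            for h in hydrogens:
                if h.residue_key != d.residue_key:
                    continue
                if np.linalg.norm(h.coords - d.coords) >= 1.3:
                    continue
                for a in acceptors:
                    d_ha = np.linalg.norm(a.coords - h.coords)
                    v1, v2 = d.coords - h.coords, a.coords - h.coords
                    theta = np.degrees(np.arccos(np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1, 1)))
                    total += (
                        oracle_block(abs(d_ha - p.hb_d_ideal),
                                     p.hb_d_inner, p.hb_d_outer)
                        * oracle_block(abs(theta - 180.0),
                                       p.hb_theta_inner, p.hb_theta_outer)
                    )
    return total


def oracle_contacts(c, kind, p=DEFAULT_PARAMS):
    polar = {"donor", "acceptor", "donor_acceptor"}
    total = 0.0
    for a in c.mhc_atoms:
        if a.element == "H":
            continue
        for b in c.peptide_atoms:
            if b.element == "H":
                continue
            if kind == "lipo":
                ok = a.atom_class == "lipophilic" and b.atom_class == "lipophilic"
            else:
                ok = (a.atom_class == "lipophilic" and b.atom_class in polar) \
                    or (b.atom_class == "lipophilic" and a.atom_class in polar)
            if not ok:
                continue
            r1 = a.vdw_radius + b.vdw_radius + p.lipo_pad
            d = np.linalg.norm(a.coords - b.coords)
            total += oracle_block(d, r1, r1 + p.lipo_width)
    return total


ROT_TABLE = {"A": 0, "G": 0, "P": 0, "S": 1, "C": 1, "T": 1, "V": 1,
             "D": 2, "N": 2, "I": 2, "L": 2, "F": 2, "W": 2, "H": 2, "Y": 2,
             "E": 3, "Q": 3, "M": 3, "K": 4, "R": 4}


# ---------------------------------------------------------------------------
# block
# ---------------------------------------------------------------------------

class TestBlock:
    @pytest.mark.parametrize("x,expected", [
        (0.1, 1.0), (0.45, 0.5), (0.7, 0.0),
    ])
    def test_ramp_values(self, x, expected):
        assert block(x, 0.25, 0.65) == pytest.approx(expected)

    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            block(0.5, 1.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-5, 5), st.floats(-2, 2), st.floats(0.01, 3))
    def test_bounded_and_monotone(self, x, x1, width):
        x2 = x1 + width
        w = block(x, x1, x2)
        assert 0.0 <= w <= 1.0
        assert block(x + 0.1, x1, x2) <= w + 1e-12


# ---------------------------------------------------------------------------
# HB
# ---------------------------------------------------------------------------

def _hbond_pair(d=1.85, theta=180.0, chain_roles=("A", "C")):
    """Donor N-H on one chain, acceptor O on the other, given geometry."""
    mhc_chain, pep_chain = chain_roles
    n = build_atom("N", "N", [0, 0, 0], res="GLY", chain=pep_chain,
                   atom_class="donor")
    h = build_atom("H", "H", [0, -1.01, 0], res="GLY", chain=pep_chain,
                   atom_class="hydrogen")
    theta_r = np.deg2rad(theta)
    o_pos = h.coords + d * np.array([np.sin(theta_r), np.cos(theta_r), 0.0])
    o = build_atom("O", "O", o_pos, res="GLY", chain=mhc_chain,
                   atom_class="acceptor")
    return n, h, o


class TestHB:
    def test_ideal_bond_scores_one(self):
        n, h, o = _hbond_pair()
        c = bare_complex([o], [n, h], "G")
        assert hb_term(c) == pytest.approx(1.0, abs=1e-12)

    def test_intramolecular_pairs_excluded(self):
        n, h, o = _hbond_pair()
        for a in (n, h, o):
            a.chain_id = "A"
        c = bare_complex([n, h, o], [build_atom("CB", "C", [50, 0, 0],
                                                chain="C",
                                                atom_class="lipophilic")], "A")
        assert hb_term(c) == 0.0

    def test_multiple_bonds_match_triple_loop_oracle(self):
        mhc, pep = [], []
        for i, (d, theta) in enumerate([(1.85, 180), (2.2, 160), (2.4, 120)]):
            n, h, o = _hbond_pair(d, theta)
            for a in (n, h):
                a.coords = a.coords + np.array([30.0 * i, 0, 0])
                a.residue_seq = i + 1
            o.coords = o.coords + np.array([30.0 * i, 0, 0])
            o.residue_seq = i + 1
            pep.extend([n, h])
            mhc.append(o)
        c = bare_complex(mhc, pep, "GGG")
        assert hb_term(c) == pytest.approx(oracle_hb(c), abs=1e-9)

    def test_untyped_atoms_raise(self):
        n, h, o = _hbond_pair()
        n.atom_class = None
        with pytest.raises(StructureError):
            hb_term(bare_complex([o], [n, h], "G"))


# ---------------------------------------------------------------------------
# LIPO / BP
# ---------------------------------------------------------------------------

class TestContacts:
    def test_pair_at_inner_bound_scores_one(self):
        r1 = 2 * 1.70 + 0.5
        a = build_atom("CB", "C", [0, 0, 0], atom_class="lipophilic")
        b = build_atom("CB", "C", [r1, 0, 0], chain="C",
                       atom_class="lipophilic")
        assert lipo_term(bare_complex([a], [b])) == pytest.approx(1.0)

    def test_pair_beyond_support_scores_zero(self):
        r1 = 2 * 1.70 + 0.5
        a = build_atom("CB", "C", [0, 0, 0], atom_class="lipophilic")
        b = build_atom("CB", "C", [r1 + 3.0 + 1e-6, 0, 0], chain="C",
                       atom_class="lipophilic")
        assert lipo_term(bare_complex([a], [b])) == 0.0

    def test_bp_carbonyl_contact(self):
        o = build_atom("O", "O", [0, 0, 0], chain="C", atom_class="acceptor")
        cb = build_atom("CB", "C", [1.4 + 1.7 + 0.5, 0, 0],
                        atom_class="lipophilic")
        assert bp_term(bare_complex([cb], [o])) == pytest.approx(1.0)

    def test_all_lipophilic_gives_zero_bp(self):
        a = build_atom("CB", "C", [0, 0, 0], atom_class="lipophilic")
        b = build_atom("CB", "C", [4.0, 0, 0], chain="C",
                       atom_class="lipophilic")
        assert bp_term(bare_complex([a], [b])) == 0.0

    def test_random_fixture_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(7)
        classes = ["lipophilic", "acceptor", "donor", "polar_neutral"]
        mhc = [
            build_atom("X", "C", rng.uniform(-6, 6, 3), seq=i,
                       atom_class=classes[i % 4])
            for i in range(10)
        ]
        pep = [
            build_atom("Y", "O" if i % 3 == 0 else "C",
                       rng.uniform(-6, 6, 3), seq=i, chain="C",
                       atom_class=classes[(i + 1) % 4])
            for i in range(10)
        ]
        c = bare_complex(mhc, pep)
        assert lipo_term(c) == pytest.approx(oracle_contacts(c, "lipo"),
                                             abs=1e-9)
        assert bp_term(c) == pytest.approx(oracle_contacts(c, "bp"),
                                           abs=1e-9)


# ---------------------------------------------------------------------------
# ROT
# ---------------------------------------------------------------------------

class TestRot:
    @pytest.mark.parametrize("seq,expected", [
        ("GAGA", 0), ("KKKK", 16), ("P", 0),
    ])
    def test_examples(self, seq, expected):
        assert rot_term(seq) == expected

    def test_table_sum_oracle(self):
        seq = "TLTSCNTSV"
        assert rot_term(seq) == sum(ROT_TABLE[x] for x in seq)

    def test_unknown_letter_raises(self):
        with pytest.raises(DataError):
            rot_term("AXZ")

    def test_depends_only_on_sequence(self, mixed_fixture_complex):
        c, _ = mixed_fixture_complex
        moved = c.copy()
        for a in moved.all_atoms:
            a.coords = a.coords + 5.0
        assert rot_term(c.peptide_sequence) == rot_term(moved.peptide_sequence)


# ---------------------------------------------------------------------------
# DESOLV
# ---------------------------------------------------------------------------

class TestDesolv:
    def test_distant_peptide_has_no_desolvation(self):
        spec = FixtureSpec(lipo_distances=(30.0,), seed=0)
        c, _ = toy_complex_structure(spec)
        assert abs(desolv_term(c)) < 1e-6

    def test_external_backend_passthrough(self, mixed_fixture_complex):
        c, _ = mixed_fixture_complex
        assert desolv_term(
            c, backend="external", external_table={"complexX": -12.3},
            complex_id="complexX",
        ) == -12.3
        with pytest.raises(DataError):
            desolv_term(c, backend="external", external_table={},
                        complex_id="missing")

    def test_two_sphere_closed_form(self):
        d = 4.0
        c, _ = toy_complex_structure(FixtureSpec(lipo_distances=(d,), seed=0))
        params = TermParams(sasa_points=5000)
        r_eff = 1.70 + params.probe_radius
        cap_height = r_eff - d / 2.0  # equal spheres
        lost_area = 2 * (2 * np.pi * r_eff * cap_height)
        expected = -DEFAULT_SIGMA["lipophilic"] * lost_area
        assert desolv_term(c, params=params) == pytest.approx(
            expected, rel=0.02
        )


# ---------------------------------------------------------------------------
# composition & invariances
# ---------------------------------------------------------------------------

class TestComposition:
    def test_vector_equals_individual_terms(self, mixed_fixture_complex):
        c, _ = mixed_fixture_complex
        tv = compute_terms(c)
        assert tv.hb == hb_term(c)
        assert tv.lipo == lipo_term(c)
        assert tv.bp == bp_term(c)
        assert tv.rot == rot_term(c.peptide_sequence)
        assert tv.desolv == desolv_term(c)

    def test_deterministic(self, mixed_fixture_complex):
        c, _ = mixed_fixture_complex
        a = compute_terms(c).as_array()
        b = compute_terms(c).as_array()
        assert np.array_equal(a, b)

    def test_rigid_motion_invariance(self, mixed_fixture_complex):
        c, _ = mixed_fixture_complex
        moved = c.copy()
        R = Rotation.from_euler("zyx", [17, -40, 113], degrees=True)
        shift = np.array([3.0, -8.0, 12.0])
        for a in moved.all_atoms:
            a.coords = R.apply(a.coords) + shift
        before = compute_terms(c).as_array()
        after = compute_terms(moved).as_array()
        # geometric kernels are exactly invariant; the sampled-surface
        # desolvation term only to quadrature accuracy
        assert np.allclose(before[:4], after[:4], atol=1e-6)
        assert after[4] == pytest.approx(before[4], rel=0.02, abs=0.05)

    def test_separation_never_increases_contact_terms(self):
        spec = FixtureSpec(
            hbond_geometries=((1.85, 180.0),),
            lipo_distances=(3.9,), bp_distances=(3.6,), seed=4,
        )
        c, _ = toy_complex_structure(spec)
        # peptide lies entirely above the MHC along +y in this layout
        values = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            moved = c.copy()
            for a in moved.peptide_atoms:
                a.coords = a.coords + np.array([0.0, shift, 0.0])
            values.append((hb_term(moved), lipo_term(moved), bp_term(moved)))
        for prev, nxt in zip(values, values[1:]):
            assert all(n <= p + 1e-12 for p, n in zip(prev, nxt))
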