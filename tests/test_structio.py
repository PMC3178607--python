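"""Structure ingestion, protonation geometry and atom typing."""

import numpy as np
import pytest

from groovescore import _chemdata as chem
from groovescore.errors import StructureError
from groovescore.structio import (
    assign_atom_classes, place_polar_hydrogens, read_complex, write_pdb,
)

from conftest import bare_complex, build_atom, ideal_gly_dipeptide


def _pdb(lines):
    return "\n".join(lines) + "\nEND\n"


def _atom_line(serial, name, res, chain, seq, x, y, z, occ=1.0, altloc=" ",
               element=None):
    element = element or name[0]
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_f:<4s}{altloc}{res:>3s} {chain}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


def _two_chain_pdb(extra_lines=()):
    lines = [
        _atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        _atom_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
        _atom_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0),
        _atom_line(4, "O", "GLY", "A", 1, 1.3, 2.4, 0.0),
        _atom_line(5, "N", "GLY", "C", 1, 10.0, 0.0, 0.0),
        _atom_line(6, "CA", "GLY", "C", 1, 11.458, 0.0, 0.0, element="C"),
        _atom_line(7, "C", "GLY", "C", 1, 12.0, 1.4, 0.0),
        _atom_line(8, "O", "GLY", "C", 1, 11.3, 2.4, 0.0),
        _atom_line(9, "N", "ALA", "C", 2, 13.3, 1.5, 0.0),
        _atom_line(10, "CA", "ALA", "C", 2, 14.7, 2.0, 0.0, element="C"),
        _atom_line(11, "C", "ALA", "C", 2, 15.7, 0.9, 0.0),
        _atom_line(12, "O", "ALA", "C", 2, 15.4, -0.3, 0.0),
        _atom_line(13, "CB", "ALA", "C", 2, 15.0, 3.0, 1.1, element="C"),
        _atom_line(14, "N", "GLY", "C", 3, 16.9, 1.3, 0.0),
        _atom_line(15, "CA", "GLY", "C", 3, 18.0, 0.4, 0.0, element="C"),
        _atom_line(16, "C", "GLY", "C", 3, 19.3, 1.2, 0.0),
        _atom_line(17, "O", "GLY", "C", 3, 19.4, 2.4, 0.0),
    ]
    lines.extend(extra_lines)
    return _pdb(lines)


ROLES = {"A": "mhc", "C": "peptide"}


class TestReadComplex:
    def test_sequence_and_partitioning(self):
        c = read_complex(_two_chain_pdb(), ROLES)
        assert c.peptide_sequence == "GAG"
        assert len(c.mhc_atoms) == 4
        assert len(c.peptide_atoms) == 13

    def test_discarded_chain_removed(self):
        tcr = [
            _atom_line(20, "N", "GLY", "D", 1, 30.0, 0.0, 0.0),
            _atom_line(21, "CA", "GLY", "D", 1, 31.4, 0.0, 0.0, element="C"),
            _atom_line(22, "C", "GLY", "D", 1, 32.0, 1.4, 0.0),
        ]
        base = read_complex(_two_chain_pdb(), ROLES)
        with_tcr = read_complex(
            _two_chain_pdb(tcr), {**ROLES, "D": "discarded"}
        )
        assert len(with_tcr.all_atoms) == len(base.all_atoms)

    def test_waters_and_heteroatoms_removed(self):
        het = [
            "HETATM   30  O   HOH A 101      9.000   9.000   9.000"
            "  1.00  0.00           O",
        ]
        c = read_complex(_two_chain_pdb(het), ROLES)
        assert all(a.residue_name != "HOH" for a in c.all_atoms)

    def test_altloc_highest_occupancy_kept(self):
        lines = [
            _atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, 0.4, "B"),
            _atom_line(2, "N", "GLY", "A", 1, 0.5, 0.0, 0.0, 0.6, "A"),
            _atom_line(3, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
            _atom_line(4, "C", "GLY", "A", 1, 2.0, 1.4, 0.0),
            _atom_line(5, "N", "GLY", "C", 1, 10.0, 0.0, 0.0),
            _atom_line(6, "CA", "GLY", "C", 1, 11.458, 0.0, 0.0, element="C"),
            _atom_line(7, "C", "GLY", "C", 1, 12.0, 1.4, 0.0),
        ]
        c = read_complex(_pdb(lines), ROLES)
        n_atoms = [a for a in c.mhc_atoms if a.name == "N"]
        assert len(n_atoms) == 1
        assert n_atoms[0].coords[0] == pytest.approx(0.5)

    def test_altloc_tie_prefers_a(self):
        lines = [
            _atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, 0.5, "B"),
            _atom_line(2, "N", "GLY", "A", 1, 0.5, 0.0, 0.0, 0.5, "A"),
            _atom_line(3, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
            _atom_line(4, "C", "GLY", "A", 1, 2.0, 1.4, 0.0),
            _atom_line(5, "N", "GLY", "C", 1, 10.0, 0.0, 0.0),
            _atom_line(6, "CA", "GLY", "C", 1, 11.458, 0.0, 0.0, element="C"),
            _atom_line(7, "C", "GLY", "C", 1, 12.0, 1.4, 0.0),
        ]
        c = read_complex(_pdb(lines), ROLES)
        n_atom = [a for a in c.mhc_atoms if a.name == "N"][0]
        assert n_atom.coords[0] == pytest.approx(0.5)

    def test_missing_declared_chain_raises(self):
        with pytest.raises(StructureError, match="'B'"):
            read_complex(_two_chain_pdb(), {"A": "mhc", "B": "mhc",
                                            "C": "peptide"})

    def test_residue_without_backbone_raises(self):
        lines = [
            _atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
            _atom_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0),
            _atom_line(4, "CA", "GLY", "C", 1, 11.458, 0.0, 0.0, element="C"),
        ]
        with pytest.raises(StructureError, match="backbone"):
            read_complex(_pdb(lines), ROLES)

    def test_incomplete_peptide_side_chain_raises(self):
        # LEU missing its CD atoms: fine in the MHC frame, fatal in the peptide
        lines = [
            _atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
            _atom_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0),
            _atom_line(4, "N", "LEU", "C", 1, 10.0, 0.0, 0.0),
            _atom_line(5, "CA", "LEU", "C", 1, 11.458, 0.0, 0.0, element="C"),
            _atom_line(6, "C", "LEU", "C", 1, 12.0, 1.4, 0.0),
            _atom_line(7, "CB", "LEU", "C", 1, 11.9, -0.9, 1.0, element="C"),
        ]
        with pytest.raises(StructureError, match="missing side-chain"):
            read_complex(_pdb(lines), ROLES)
        # same residue on the MHC side is tolerated
        swapped = [
            _atom_line(1, "N", "LEU", "A", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "CA", "LEU", "A", 1, 1.458, 0.0, 0.0, element="C"),
            _atom_line(3, "C", "LEU", "A", 1, 2.0, 1.4, 0.0),
            _atom_line(4, "CB", "LEU", "A", 1, 1.9, -0.9, 1.0, element="C"),
            _atom_line(5, "N", "GLY", "C", 1, 10.0, 0.0, 0.0),
            _atom_line(6, "CA", "GLY", "C", 1, 11.458, 0.0, 0.0, element="C"),
            _atom_line(7, "C", "GLY", "C", 1, 12.0, 1.4, 0.0),
        ]
        read_complex(_pdb(swapped), ROLES)

    def test_roundtrip_preserves_atoms(self):
        c = read_complex(_two_chain_pdb(), ROLES)
        c2 = read_complex(write_pdb(c), ROLES)
        assert [a.name for a in c2.all_atoms] == [a.name for a in c.all_atoms]
        for a, b in zip(c.all_atoms, c2.all_atoms):
            assert np.allclose(a.coords, b.coords, atol=1e-3)


class TestPolarHydrogens:
    def test_amide_h_anti_to_previous_carbonyl(self, gly_dipeptide_complex):
        c, coords = gly_dipeptide_complex
        p = place_polar_hydrogens(c)
        h2 = [a for a in p.peptide_atoms
              if a.is_hydrogen and a.residue_seq == 2][0]
        n2 = coords[2]["N"]
        assert np.linalg.norm(h2.coords - n2) == pytest.approx(1.01, abs=0.01)
        dihedral = chem.dihedral_angle(
            h2.coords, n2, coords[1]["C"], coords[1]["O"]
        )
        assert abs(abs(dihedral) - 180.0) < 1.0

    def test_proline_gets_no_amide_hydrogen(self, gly_dipeptide_complex):
        c, _ = gly_dipeptide_complex
        for a in c.peptide_atoms:
            if a.residue_seq == 2:
                a.residue_name = "PRO"
        p = place_polar_hydrogens(c)
        assert not any(
            a.is_hydrogen and a.residue_seq == 2 for a in p.peptide_atoms
        )

    def test_heavy_atoms_never_move(self, gly_dipeptide_complex):
        c, _ = gly_dipeptide_complex
        before = {
            (a.residue_seq, a.name): a.coords.copy() for a in c.peptide_atoms
        }
        p = place_polar_hydrogens(c)
        for a in p.peptide_atoms:
            if not a.is_hydrogen:
                assert np.array_equal(a.coords, before[(a.residue_seq, a.name)])

    def test_idempotent_on_protonated_structure(self, gly_dipeptide_complex):
        c, _ = gly_dipeptide_complex
        once = place_polar_hydrogens(c)
        twice = place_polar_hydrogens(once)
        assert len(twice.all_atoms) == len(once.all_atoms)

    def test_nonstandard_residue_skipped_with_warning(
        self, gly_dipeptide_complex
    ):
        c, _ = gly_dipeptide_complex
        for a in c.peptide_atoms:
            if a.residue_seq == 2:
                a.residue_name = "XYZ"
        with pytest.warns(UserWarning, match="non-standard"):
            p = place_polar_hydrogens(c)
        assert not any(
            a.is_hydrogen and a.residue_seq == 2 for a in p.peptide_atoms
        )


class TestAtomClasses:
    @pytest.mark.parametrize("res,name,expected", [
        ("LYS", "NZ", chem.DONOR),
        ("GLY", "O", chem.ACCEPTOR),
        ("LEU", "CD1", chem.LIPOPHILIC),
        ("SER", "OG", chem.DONOR_ACCEPTOR),
        ("HIS", "ND1", chem.DONOR_ACCEPTOR),
        ("PHE", "CZ", chem.LIPOPHILIC),
        ("TYR", "CZ", chem.POLAR_NEUTRAL),
        ("MET", "SD", chem.LIPOPHILIC),
        ("GLY", "CA", chem.POLAR_NEUTRAL),
        ("PRO", "N", chem.ACCEPTOR),
        ("ASP", "OD1", chem.ACCEPTOR),
        ("ARG", "NH1", chem.DONOR),
    ])
    def test_typing_table(self, res, name, expected):
        assert chem.atom_class(res, name) == expected

    def test_total_over_standard_residues(self):
        for res in sorted(chem.STANDARD_RESIDUES):
            tpl = chem.residue_template(res)
            for name, elem in zip(tpl.atom_name, tpl.element):
                if elem == "H":
                    continue
                cls = chem.atom_class(res, name, elem)
                assert cls in (
                    chem.LIPOPHILIC, chem.DONOR, chem.ACCEPTOR,
                    chem.DONOR_ACCEPTOR, chem.POLAR_NEUTRAL,
                ), (res, name, cls)

    def test_unknown_atom_classified_other_with_warning(self):
        with pytest.warns(UserWarning):
            assert chem.atom_class("ALA", "XX9") == chem.OTHER

    def test_assign_atom_classes_types_everything(self, gly_dipeptide_complex):
        c, _ = gly_dipeptide_complex
        typed = assign_atom_classes(place_polar_hydrogens(c))
        assert all(a.atom_class is not None for a in typed.all_atoms)
        assert all(
            a.atom_class == chem.HYDROGEN
            for a in typed.all_atoms if a.element == "H"
        )
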