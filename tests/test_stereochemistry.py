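"""Restraint generation, disulfide/termini detection, hydrogen rules."""

import numpy as np
import pytest

from shelxbridge.errors import NoRestraintsWarning
from shelxbridge.fixtures import build_polypeptide
from shelxbridge.geometry import UnitCell
from shelxbridge.stereochemistry import (AMINO_ACIDS, detect_disulfides,
                                         detect_termini, hfix_for_residue,
                                         peptide_planarity, residue_library,
                                         restraints_for_residue)
from shelxbridge.structure import AtomRecord, StructureModel


def _sg(res_seq, xyz):
    return AtomRecord(name="SG", res_name="CYS", chain_id="A",
                      res_seq=res_seq, xyz_cart=np.array(xyz, dtype=float),
                      element="S")


def _peptide_model(sequence, cell=(60, 40, 40, 90, 90, 90)):
    atoms = build_polypeptide(sequence)
    return StructureModel(atoms=atoms, cell=UnitCell(*cell),
                          space_group_symbol="P 1")


class TestRestraintLibrary:
    def test_glycine_backbone_restraints(self):
        records = restraints_for_residue("GLY")
        dfix = {(r.atom_names): r.target for r in records if r.kind == "DFIX"}
        assert ("N", "CA") in dfix and ("CA", "C") in dfix \
            and ("C", "O") in dfix
        dang = {frozenset(r.atom_names) for r in records if r.kind == "DANG"}
        assert frozenset({"N", "C"}) in dang
        assert frozenset({"CA", "O"}) in dang
        assert all(r.residue_scope == "_GLY" for r in records)

    def test_unknown_residue_warns_and_returns_empty(self):
        with pytest.warns(NoRestraintsWarning):
            assert restraints_for_residue("XYZ") == []

    def test_water_exempt_no_warning(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert restraints_for_residue("HOH") == []

    def test_terminal_oxt_adds_carboxylate(self):
        records = restraints_for_residue("ALA", terminal_oxt=True)
        dfix = {r.atom_names: r.target for r in records if r.kind == "DFIX"}
        assert dfix[("C", "OXT")] == pytest.approx(1.249)
        assert dfix[("C", "O")] == pytest.approx(1.249)  # carboxylate form
        dang = {frozenset(r.atom_names) for r in records if r.kind == "DANG"}
        assert frozenset({"O", "OXT"}) in dang

    def test_all_targets_and_esds_in_physical_ranges(self):
        for name in sorted(residue_library()):
            terminal = residue_library()[name].get("kind") == "amino"
            for r in restraints_for_residue(name, terminal_oxt=terminal):
                if r.kind in ("DFIX", "DANG"):
                    assert 0.9 <= r.target <= 3.2, (name, r)
                assert 0.0 < r.esd <= 0.2, (name, r)

    def test_every_standard_amino_acid_covered(self):
        lib = residue_library()
        assert AMINO_ACIDS <= set(lib)


class TestDisulfides:
    def test_pair_inside_window(self):
        pairs = detect_disulfides([_sg(1, [0, 0, 0]), _sg(2, [2.03, 0, 0])])
        assert len(pairs) == 1

    def test_far_apart_not_paired(self):
        assert detect_disulfides([_sg(1, [0, 0, 0]),
                                  _sg(2, [4.0, 0, 0])]) == []

    def test_three_cysteines_nearest_wins(self):
        # SG1-SG2 2.03, SG2-SG3 2.04, SG1-SG3 ~3.9: only the closest pair
        atoms = [_sg(1, [0, 0, 0]), _sg(2, [2.03, 0, 0]),
                 _sg(3, [2.03 + 1.9, 0.74, 0])]
        d23 = np.linalg.norm(atoms[1].xyz_cart - atoms[2].xyz_cart)
        d13 = np.linalg.norm(atoms[0].xyz_cart - atoms[2].xyz_cart)
        assert 2.03 < d23 < 2.1 and d13 > 3.8
        pairs = detect_disulfides(atoms)
        assert len(pairs) == 1
        assert {pairs[0][0].res_seq, pairs[0][1].res_seq} == {1, 2}

    def test_order_invariance(self):
        atoms = [_sg(1, [0, 0, 0]), _sg(2, [2.03, 0, 0]),
                 _sg(3, [10, 0, 0]), _sg(4, [12.04, 0, 0])]
        forward = detect_disulfides(atoms)
        backward = detect_disulfides(list(reversed(atoms)))
        as_sets = lambda prs: {frozenset((a.res_seq, b.res_seq))
                               for a, b in prs}
        assert as_sets(forward) == as_sets(backward)
        assert len(forward) == 2


class TestTermini:
    def test_single_chain_termini(self):
        model = _peptide_model("GAV")
        segments = detect_termini(model)
        assert len(segments) == 1
        assert segments[0].n_terminal[1] == 1
        assert segments[0].c_terminal[1] == 3
        assert segments[0].has_oxt  # builder adds OXT to the last residue

    def test_gap_splits_into_segments(self):
        model = _peptide_model("GAVGA")
        shift = np.array([10.0, 0.0, 0.0])
        for atom in model.atoms:
            if atom.res_seq > 3:
                atom.xyz_cart = atom.xyz_cart + shift
        segments = detect_termini(model)
        assert len(segments) == 2
        assert [s.n_terminal[1] for s in segments] == [1, 4]
        assert [s.c_terminal[1] for s in segments] == [3, 5]

    def test_waters_ignored(self):
        model = _peptide_model("GA")
        model.atoms.append(AtomRecord(
            name="O", res_name="HOH", chain_id="A", res_seq=101,
            xyz_cart=np.array([30.0, 0, 0]), element="O", is_hetatm=True))
        segments = detect_termini(model)
        assert len(segments) == 1
        assert segments[0].c_terminal[1] == 2


class TestPeptidePlanarity:
    def test_flat_count_is_links(self):
        assert len(peptide_planarity(_peptide_model("GAV"))) == 2
        assert len(peptide_planarity(_peptide_model("G"))) == 0

    @pytest.mark.parametrize("sequence", ["GA", "GAVS", "ACDEFG"])
    def test_flat_count_n_minus_one(self, sequence):
        records = peptide_planarity(_peptide_model(sequence))
        assert len(records) == len(sequence) - 1
        for r in records:
            assert r.kind == "FLAT"
            assert len(r.atom_names) == 5

    def test_no_flat_across_break(self):
        model = _peptide_model("GAVGA")
        for atom in model.atoms:
            if atom.res_seq > 3:
                atom.xyz_cart = atom.xyz_cart + np.array([10.0, 0, 0])
        assert len(peptide_planarity(model)) == 3  # 2 links + 1 link


class TestHfix:
    def test_valine_complete_block(self):
        rules = hfix_for_residue(
            "VAL", {"N", "CA", "C", "O", "CB", "CG1", "CG2"})
        assert [(r.hfix_code, r.parent_atoms, r.commented) for r in rules] == [
            (43, ("N",), True),
            (13, ("CA", "CB"), True),
            (33, ("CG1", "CG2"), True),
        ]

    def test_missing_atoms_become_active_hfix_zero(self):
        rules = hfix_for_residue("VAL", {"N", "CA", "C", "O", "CB"})
        commented = [r for r in rules if r.commented]
        active = [r for r in rules if not r.commented]
        assert [(r.hfix_code, r.parent_atoms) for r in commented] == [
            (43, ("N",)), (13, ("CA", "CB"))]
        assert len(active) == 1
        assert active[0].hfix_code == 0
        assert set(active[0].parent_atoms) == {"CG1", "CG2"}

    def test_water_has_no_rules(self):
        assert hfix_for_residue("HOH") == []

    def test_n_terminus_gets_ammonium(self):
        rules = hfix_for_residue("GLY", {"N", "CA", "C", "O"},
                                 n_terminal=True)
        codes = {r.hfix_code for r in rules}
        assert 33 in codes and 43 not in codes

    def test_rule_count_depends_only_on_sequence(self):
        full = {"N", "CA", "C", "O", "CB", "OG"}
        assert hfix_for_residue("SER", full) == hfix_for_residue("SER", full)

    def test_disulfide_suppresses_thiol(self):
        rules = hfix_for_residue("CYS", {"N", "CA", "C", "O", "CB", "SG"},
                                 suppress={"SG"})
        assert all(147 != r.hfix_code for r in rules)
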