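"""Instruction-document assembly: cards, ordering, grammar, idempotence."""

import numpy as np
import pytest

from shelxbridge.assembly import (InsDocument, assemble, emit_atom_card,
                                  emit_global_adp_cards, emit_resi_blocks)
from shelxbridge.errors import AssemblyError
from shelxbridge.geometry import UnitCell
from shelxbridge.pipeline import RunConfig, run
from shelxbridge.reflections import read_refln_cif
from shelxbridge.scattering import build_sfac
from shelxbridge.structure import AtomRecord, StructureModel, read_pdb
from shelxbridge.symmetry import lookup_space_group


def _atom(name="CA", element="C", res_seq=21, res_name="TOL", chain="A",
          xyz=(1.0, 2.0, 3.0), occupancy=1.0, b_iso=15.0, alt_loc=" "):
    return AtomRecord(name=name, res_name=res_name, chain_id=chain,
                      res_seq=res_seq, xyz_cart=np.array(xyz, dtype=float),
                      occupancy=occupancy, b_iso=b_iso, element=element,
                      alt_loc=alt_loc)


def _model(atoms, chains_cell=(10, 20, 30)):
    return StructureModel(atoms=atoms, cell=UnitCell(*chains_cell),
                          space_group_symbol="P 1")


class TestResiBlocks:
    def test_multi_chain_form_includes_chain(self):
        atoms = [_atom(chain="A"), _atom(chain="B", res_seq=22)]
        cards = emit_resi_blocks(_model(atoms), ["C"])
        resi = [c for c in cards if c.keyword == "RESI"]
        assert resi[0].payload == "TOL A:21"
        assert resi[1].payload == "TOL B:22"

    def test_single_chain_form_omits_chain(self):
        cards = emit_resi_blocks(_model([_atom()]), ["C"])
        resi = [c for c in cards if c.keyword == "RESI"]
        assert resi[0].payload == "TOL 21"

    def test_out_of_range_number_refused(self):
        with pytest.raises(AssemblyError):
            emit_resi_blocks(_model([_atom(res_seq=10000)]), ["C"])

    def test_two_conformers_tied_to_free_variable(self):
        atoms = [_atom(alt_loc="A", occupancy=0.6),
                 _atom(alt_loc="B", occupancy=0.4)]
        cards = emit_resi_blocks(_model(atoms), ["C"])
        texts = [c.text for c in cards]
        assert "PART 1" in texts and "PART 2" in texts and "PART 0" in texts
        occ_codes = [c.payload.split()[4] for c in cards
                     if c.keyword == "CA"]
        assert occ_codes == ["21.00000", "-21.00000"]


class TestAtomCard:
    def test_full_occupancy_isotropic_coding(self):
        cell = UnitCell(10, 20, 30)
        card = emit_atom_card(_atom(xyz=(5.0, 10.0, 15.0), b_iso=20.0),
                              cell, sfac_index=1)
        fields = card.payload.split()
        assert card.keyword == "CA"
        assert fields[0] == "1"
        assert fields[1:4] == ["0.500000", "0.500000", "0.500000"]
        assert fields[4] == "11.00000"
        assert float(fields[5]) == pytest.approx(20.0 / (8 * np.pi ** 2),
                                                 abs=1e-5)

    def test_anisotropic_atom_carries_six_u(self):
        cell = UnitCell(10, 20, 30)
        atom = _atom()
        atom.u_aniso_cart = np.diag([0.04, 0.05, 0.06])
        card = emit_atom_card(atom, cell, sfac_index=2)
        fields = card.payload.split()
        assert len(fields) == 11  # sfac, xyz, occ, six U
        assert float(fields[5]) == pytest.approx(0.04)
        assert float(fields[7]) == pytest.approx(0.06)


class TestGlobalAdp:
    def test_rigu_and_xnpd_always_active(self):
        cards = emit_global_adp_cards()
        texts = [c.text for c in cards]
        assert "RIGU" in texts
        assert "XNPD 0.01" in texts

    def test_anis_delu_simu_offered_as_comments(self):
        cards = emit_global_adp_cards()
        commented = {c.keyword for c in cards if c.commented}
        assert {"ANIS", "DELU", "SIMU"} <= commented

    def test_deterministic_order(self):
        assert [c.text for c in emit_global_adp_cards()] == \
            [c.text for c in emit_global_adp_cards()]


def _assembled(model, refl_text=None):
    setting = lookup_space_group(model.space_group_symbol)
    sfac, unit = build_sfac(model, len(setting.operators),
                            setting.centering_multiplicity)
    rset = read_refln_cif(refl_text) if refl_text else None
    return assemble(model, setting, sfac, unit, reflection_set=rset)


AMPLITUDE_LOOP = """data_t
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.F_meas_au
_refln.F_meas_sigma_au
1 0 0 10.0 0.5
"""

INTENSITY_LOOP = """data_t
loop_
_refln.index_h
_refln.index_k
_refln.index_l
_refln.intensity_meas
_refln.intensity_sigma
1 0 0 10.0 0.5
"""


class TestAssemble:
    def test_card_order_and_grammar(self):
        doc = _assembled(_model([_atom()]))
        keywords = doc.keywords()
        for kw in ("TITL", "CELL", "ZERR", "LATT", "SFAC", "UNIT",
                   "RIGU", "XNPD", "RESI", "HKLF", "END"):
            assert kw in keywords
        assert keywords.index("TITL") < keywords.index("CELL") \
            < keywords.index("ZERR") < keywords.index("LATT") \
            < keywords.index("SFAC") < keywords.index("UNIT") \
            < keywords.index("RESI") < keywords.index("HKLF") \
            < keywords.index("END")

    def test_intensities_give_hklf4(self):
        doc = _assembled(_model([_atom()]), INTENSITY_LOOP)
        assert doc.find("HKLF")[0].payload == "4"

    def test_amplitudes_give_hklf3(self):
        doc = _assembled(_model([_atom()]), AMPLITUDE_LOOP)
        assert doc.find("HKLF")[0].payload == "3"

    def test_assembly_is_idempotent(self):
        model = _model([_atom()])
        assert _assembled(model).text() == _assembled(model).text()

    def test_reparse_recovers_atoms(self, run_dir):
        report = run(RunConfig(pdb_path=str(run_dir / "fix.pdb"),
                               hkl_path=str(run_dir / "fix.cif"),
                               output_basename=str(run_dir / "fix")))
        assert report.ok
        ins = (run_dir / "fix.ins").read_text()
        model = read_pdb((run_dir / "fix.pdb").read_text())
        resi_lines = [l for l in ins.splitlines() if l.startswith("RESI")]
        assert len(resi_lines) == len(model.residues())
        numbers = [int(l.split()[2].split(":")[-1]) for l in resi_lines]
        assert numbers == [k[1] for k, _ in model.residues()]
        # fractional coordinates recoverable at emitted precision
        frac_ca = model.cell.cart_to_frac(model.atoms[1].xyz_cart)
        ca_line = next(l for l in ins.splitlines() if l.startswith("CA "))
        emitted = [float(v) for v in ca_line.split()[2:5]]
        np.testing.assert_allclose(emitted, frac_ca, atol=5e-7)

    def test_scoped_cards_reference_existing_residues(self, run_dir):
        run(RunConfig(pdb_path=str(run_dir / "fix.pdb"),
                      output_basename=str(run_dir / "fix")))
        ins = (run_dir / "fix.ins").read_text()
        resi_names = {l.split()[1] for l in ins.splitlines()
                      if l.startswith("RESI")}
        for line in ins.splitlines():
            head = line.split()[0] if line.split() else ""
            if "_" in head and not head.startswith("REM"):
                scope = head.split("_", 1)[1]
                if not scope.isdigit():
                    assert scope in resi_names


class TestGrammarChecker:
    def test_duplicate_cell_detected(self):
        doc = _assembled(_model([_atom()]))
        from shelxbridge.assembly import _check_grammar
        from shelxbridge.cards import Card
        doc.cards.insert(2, Card("CELL", "1.0 10 10 10 90 90 90"))
        with pytest.raises(AssemblyError):
            _check_grammar(doc, ["C"])

    def test_symm_must_follow_latt(self):
        model = StructureModel(atoms=[_atom()], cell=UnitCell(10, 20, 30),
                               space_group_symbol="P 21 21 21")
        doc = _assembled(model)
        from shelxbridge.assembly import _check_grammar
        symm = doc.cards.pop(doc.keywords().index("SYMM"))
        doc.cards.append(symm)
        with pytest.raises(AssemblyError):
            _check_grammar(doc, ["C"])
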