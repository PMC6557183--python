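"""Synthetic-fixture generation and the end-to-end conversion pipeline."""

import numpy as np
import pytest

from shelxbridge.errors import (NotFoundError, UnknownDefectError)
from shelxbridge.fixtures import DEFECTS, FixtureSpec, generate_fixture
from shelxbridge.pipeline import RunConfig, fetch_by_code, run
from shelxbridge.structure import read_pdb


class TestFixtureGeneration:
    def test_gv_fixture_atom_count(self):
        spec = FixtureSpec(sequence="GV", seed=42)
        pdb_text, _ = generate_fixture(spec)
        model = read_pdb(pdb_text)
        # Gly 4 + Val 7 heavy atoms + OXT + 4 waters
        assert len(model.atoms) == 16
        names = {(a.res_name, a.name) for a in model.atoms}
        assert ("VAL", "OXT") in names
        assert sum(1 for a in model.atoms if a.res_name == "HOH") == 4

    def test_seeded_generation_is_byte_identical(self):
        spec = FixtureSpec(sequence="GVA", seed=7, n_reflections=50)
        assert generate_fixture(spec) == generate_fixture(spec)

    def test_different_seeds_differ(self):
        a = generate_fixture(FixtureSpec(sequence="GV", seed=1))
        b = generate_fixture(FixtureSpec(sequence="GV", seed=2))
        assert a != b

    def test_zero_free_fraction_has_no_free_flags(self):
        spec = FixtureSpec(sequence="G", free_fraction=0.0, seed=3,
                           n_reflections=40)
        _, cif = generate_fixture(spec)
        data_lines = [l for l in cif.splitlines()
                      if l and not l.startswith(("_", "data_", "loop_", "#"))]
        assert all(l.split()[-1] == "o" for l in data_lines)

    def test_unknown_defect_rejected(self):
        with pytest.raises(UnknownDefectError):
            FixtureSpec(sequence="G", defects=("bogus",))

    def test_reflections_respect_resolution_limit(self):
        spec = FixtureSpec(sequence="G", seed=5, n_reflections=60)
        _, cif = generate_fixture(spec)
        from shelxbridge.geometry import UnitCell
        cell = UnitCell(*spec.cell)
        for line in cif.splitlines():
            parts = line.split()
            if len(parts) == 6 and not line.startswith("_"):
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                assert cell.d_spacing((h, k, l)) >= spec.d_min
                assert float(parts[3]) > 0


def _run_fixture(tmp_path, defects=(), sequence="GV", **config_kwargs):
    spec = FixtureSpec(sequence=sequence, space_group="P 21 21 21",
                       seed=11, n_reflections=60, defects=tuple(defects))
    pdb_text, cif_text = generate_fixture(spec)
    (tmp_path / "in.pdb").write_text(pdb_text)
    (tmp_path / "in.cif").write_text(cif_text)
    config = RunConfig(pdb_path=str(tmp_path / "in.pdb"),
                       hkl_path=str(tmp_path / "in.cif"),
                       output_basename=str(tmp_path / "out"),
                       **config_kwargs)
    return run(config)


class TestPipeline:
    def test_clean_fixture_writes_both_files(self, tmp_path):
        report = _run_fixture(tmp_path)
        assert report.ok
        assert (tmp_path / "out.ins").exists()
        assert (tmp_path / "out.hkl").exists()
        assert report.n_atoms == 16
        assert report.n_reflections == 60

    def test_element_x_is_fatal_no_ins_written(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["element_x"])
        assert not report.ok
        assert any("unknown element" in e for e in report.errors)
        assert not (tmp_path / "out.ins").exists()

    def test_digit_residue_name_warns_but_continues(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["digit_residue_name"])
        assert report.ok
        assert any("digits" in w for w in report.warnings)
        assert (tmp_path / "out.ins").exists()

    def test_digit_residue_name_interactive_rename(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["digit_residue_name"],
                              interactive=True, prompter=lambda msg: "LIG")
        assert report.ok
        ins = (tmp_path / "out.ins").read_text()
        assert "RESI LIG" in ins
        assert not any("digits" in w for w in report.warnings)

    def test_multi_model_is_fatal(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["extra_model"])
        assert any("multiple models" in e for e in report.errors)

    def test_missing_sigma_is_fatal(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["missing_sigma"])
        assert any("incomplete reflection data" in e for e in report.errors)

    def test_oversized_index_is_fatal(self, tmp_path):
        report = _run_fixture(tmp_path, defects=["oversized_index"])
        assert any("hkl format overflow" in e for e in report.errors)

    def test_each_defect_yields_exactly_its_diagnostic(self, tmp_path):
        expected = {
            "digit_residue_name": ("warning", "digits"),
            "element_x": ("error", "unknown element"),
            "extra_model": ("error", "multiple models"),
            "missing_sigma": ("error", "incomplete reflection data"),
            "oversized_index": ("error", "hkl format overflow"),
        }
        assert set(expected) == set(DEFECTS)
        for defect, (channel, token) in expected.items():
            sub = tmp_path / defect
            sub.mkdir()
            report = _run_fixture(sub, defects=[defect])
            if channel == "error":
                assert len(report.errors) == 1, defect
                assert token in report.errors[0]
            else:
                assert report.ok
                assert any(token in w for w in report.warnings)

    def test_free_r_flags_survive_end_to_end(self, tmp_path):
        spec = FixtureSpec(sequence="GV", seed=9, n_reflections=100,
                           free_fraction=0.1)
        pdb_text, cif_text = generate_fixture(spec)
        (tmp_path / "in.pdb").write_text(pdb_text)
        (tmp_path / "in.cif").write_text(cif_text)
        report = run(RunConfig(pdb_path=str(tmp_path / "in.pdb"),
                               hkl_path=str(tmp_path / "in.cif"),
                               output_basename=str(tmp_path / "out")))
        assert report.ok
        hkl = (tmp_path / "out.hkl").read_text()
        free_lines = [l for l in hkl.splitlines()
                      if l[28:32].strip() == "-1"]
        assert len(free_lines) == 10 == report.n_free


class TestFetch:
    def test_injected_pair_returned(self):
        def fetcher(url):
            return "PDBTEXT" if url.endswith(".pdb") else "CIFTEXT"
        coords, sf = fetch_by_code("1abc", fetcher=fetcher)
        assert (coords, sf) == ("PDBTEXT", "CIFTEXT")

    def test_injected_404_raises(self):
        def fetcher(url):
            raise NotFoundError(url)
        with pytest.raises(NotFoundError):
            fetch_by_code("1abc", fetcher=fetcher)

    def test_coordinates_only_warns_downstream(self, tmp_path, gv_texts):
        pdb_text, _ = gv_texts

        def fetcher(url):
            if url.endswith(".pdb"):
                return pdb_text
            raise NotFoundError(url)
        report = run(RunConfig(pdb_code="1abc", fetcher=fetcher,
                               output_basename=str(tmp_path / "out")))
        assert report.ok
        assert any("no reflection data" in w for w in report.warnings)
        assert (tmp_path / "out.ins").exists()
        assert not (tmp_path / "out.hkl").exists()

    def test_config_requires_exactly_one_source(self):
        with pytest.raises(ValueError):
            RunConfig(pdb_path="x.pdb", pdb_code="1abc")
        with pytest.raises(ValueError):
            RunConfig(pdb_code="toolong5")


class TestCli:
    def test_cli_converts_local_files(self, tmp_path, gv_texts, capsys):
        from shelxbridge.cli import main
        pdb_text, cif_text = gv_texts
        (tmp_path / "fix.pdb").write_text(pdb_text)
        (tmp_path / "fix.cif").write_text(cif_text)
        code = main([str(tmp_path / "fix.pdb"),
                     "--hkl", str(tmp_path / "fix.cif"),
                     "-o", str(tmp_path / "fix")])
        assert code == 0
        out = capsys.readouterr().out
        assert "fix.ins" in out and "fix.hkl" in out

    def test_cli_reports_failure_exit_code(self, tmp_path, capsys):
        spec = FixtureSpec(sequence="G", seed=1, defects=("element_x",))
        pdb_text, _ = generate_fixture(spec)
        (tmp_path / "bad.pdb").write_text(pdb_text)
        from shelxbridge.cli import main
        assert main([str(tmp_path / "bad.pdb"),
                     "-o", str(tmp_path / "bad")]) == 1
        assert "unknown element" in capsys.readouterr().out
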