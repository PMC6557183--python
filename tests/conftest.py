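import pytest

from shelxbridge import FixtureSpec, generate_fixture, read_pdb


@pytest.fixture(scope="session")
def gv_texts():
    """Clean two-residue (Gly-Val) fixture: PDB + reflection mmCIF text."""
    spec = FixtureSpec(sequence="GV", space_group="P 21 21 21", seed=42,
                       n_reflections=120, free_fraction=0.05)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def gv_model(gv_texts):
    return read_pdb(gv_texts[0])


@pytest.fixture()
def run_dir(tmp_path, gv_texts):
    """Directory with the clean fixture written to disk."""
    pdb_text, cif_text = gv_texts
    (tmp_path / "fix.pdb").write_text(pdb_text)
    (tmp_path / "fix.cif").write_text(cif_text)
    return tmp_path
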