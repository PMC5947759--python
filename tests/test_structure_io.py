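import numpy as np
import pytest

from mrforge.structure_io import (Atom, Chain, Residue, Structure,
                                  TopologyError, prepare_input, read_pdb,
                                  write_models)


def _pdb_line(serial, name, res, chain, seq, x, y, z, occ=1.0, b=10.0,
              element=" C", altloc=" ", record="ATOM  "):
    return (f"{record}{serial:5d} {name:<4s}{altloc}{res:<3s} {chain}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}")


THREE_RES = "\n".join(
    [_pdb_line(i * 2 + 1, " N", "ALA", "A", i + 1, i * 3.8, 0, 0, element="N")
     for i in range(3)] +
    [_pdb_line(i * 2 + 2, " CA", "ALA", "A", i + 1, i * 3.8 + 1.5, 0, 0)
     for i in range(3)] + ["END"]) + "\n"


def test_read_simple_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RES)
    s = read_pdb(p)
    assert len(s.chains) == 1
    assert s.n_residues == 3
    assert s.n_models == 1


def test_read_multi_model(tmp_path):
    block = "\n".join(_pdb_line(i + 1, " CA", "GLY", "A", i + 1, i * 3.8, 0, 0)
                      for i in range(3))
    text = "".join(f"MODEL {m}\n{block}\nENDMDL\n" for m in range(1, 6)) + "END\n"
    p = tmp_path / "multi.pdb"
    p.write_text(text)
    s = read_pdb(p)
    assert s.n_models == 5


def test_inconsistent_model_topology_rejected(tmp_path):
    block = "\n".join(_pdb_line(i + 1, " CA", "GLY", "A", i + 1, i * 3.8, 0, 0)
                      for i in range(3))
    short = "\n".join(block.splitlines()[:2])
    p = tmp_path / "bad.pdb"
    p.write_text(f"MODEL 1\n{block}\nENDMDL\nMODEL 2\n{short}\nENDMDL\nEND\n")
    with pytest.raises(TopologyError):
        read_pdb(p)


def test_read_missing_and_empty_files(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_pdb(tmp_path / "absent.pdb")
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(Exception):
        read_pdb(p)


def test_prepare_input_mse_reverted(tmp_path):
    lines = [
        _pdb_line(1, " N", "MSE", "A", 1, 0, 0, 0, element="N", record="HETATM"),
        _pdb_line(2, " CA", "MSE", "A", 1, 1.5, 0, 0, record="HETATM"),
        _pdb_line(3, " SE", "MSE", "A", 1, 3.0, 1, 0, element="SE", record="HETATM"),
        "END"]
    p = tmp_path / "mse.pdb"
    p.write_text("\n".join(lines) + "\n")
    out = prepare_input(read_pdb(p), "A")
    res = out.chains[0].residues[0]
    assert res.name == "MET"
    sd = res.get("SD")
    assert sd is not None and sd.element == "S"
    assert res.get("SE") is None


def test_prepare_input_altloc_and_waters(tmp_path):
    lines = [
        _pdb_line(1, " CA", "ALA", "A", 1, 0.0, 0, 0, occ=0.6, altloc="A"),
        _pdb_line(2, " CA", "ALA", "A", 1, 9.0, 0, 0, occ=0.4, altloc="B"),
        _pdb_line(3, " O", "HOH", "A", 2, 5, 5, 5, element="O", record="HETATM"),
        "END"]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    out = prepare_input(read_pdb(p), "A")
    assert out.n_residues == 1                      # water gone
    ca = out.chains[0].residues[0].get("CA")
    assert ca.occupancy == pytest.approx(0.6)       # conformer A kept
    assert ca.altloc == ""
    assert ca.position[0] == pytest.approx(0.0)


def test_prepare_input_missing_chain(helix_tail30):
    with pytest.raises(ValueError, match="chain"):
        prepare_input(helix_tail30, "Z")


def test_prepare_input_idempotent(helix_tail30):
    once = prepare_input(helix_tail30, "A")
    twice = prepare_input(once, "A")
    assert np.allclose(once.coords(), twice.coords())
    assert [r.name for _, r in once.iter_residues()] == \
           [r.name for _, r in twice.iter_residues()]


def test_write_read_roundtrip(tmp_path, helix_tail30):
    p = tmp_path / "h.pdb"
    write_models([helix_tail30], p)
    back = read_pdb(p)
    assert back.n_atoms == helix_tail30.n_atoms
    assert np.abs(back.coords() - helix_tail30.coords()).max() <= 5e-4 + 1e-9
    # idempotency at fixed precision: a second round-trip is exact
    p2 = tmp_path / "h2.pdb"
    write_models([back], p2)
    again = read_pdb(p2)
    assert np.array_equal(again.coords(), back.coords())


def test_write_multi_model_roundtrip(tmp_path, helix_tail30):
    rng = np.random.default_rng(0)
    models = [helix_tail30.with_coords(helix_tail30.coords() + rng.normal(0, 1, (helix_tail30.n_atoms, 3)))
              for _ in range(30)]
    p = tmp_path / "ens.pdb"
    write_models(models, p, multi_model=True)
    back = read_pdb(p)
    assert back.n_models == 30
    text = p.read_text()
    assert text.count("MODEL ") == 30 and text.count("ENDMDL") == 30


def test_write_fixed_width_rounding(tmp_path):
    s = Structure([Chain("A", [Residue("GLY", 1, atoms=[
        Atom("CA", "C", [1.23456, 0, 0])])])])
    p = tmp_path / "r.pdb"
    write_models([s], p)
    assert "   1.235" in p.read_text()


def test_write_errors(tmp_path, helix15):
    with pytest.raises(ValueError):
        write_models([], tmp_path / "x.pdb")
    with pytest.raises(ValueError):
        write_models([helix15, helix15], tmp_path / "x.pdb", multi_model=False)


def test_single_model_write_has_no_model_records(tmp_path, helix15):
    p = tmp_path / "one.pdb"
    write_models([helix15], p)
    assert "MODEL" not in p.read_text()


def test_subset_residues_and_atom_invariants(helix_tail30):
    sub = helix_tail30.subset_residues({1, 2, 3})
    assert sub.n_residues == 3
    assert {r.seq_id for _, r in sub.iter_residues()} == {1, 2, 3}


def test_atom_validation():
    with pytest.raises(ValueError):
        Atom("CA", "C", [np.nan, 0, 0])
    with pytest.raises(ValueError):
        Atom("CA", "C", [0, 0, 0], occupancy=1.5)
    with pytest.raises(ValueError):
        Atom("CA", "", [0, 0, 0])
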