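import numpy as np
import pytest

from mrforge.metrics import (atom_sasa, bfactor_profile, sasa_profile,
                             wcn_profile, wcn_raw, _fibonacci_sphere)
from mrforge.structure_io import Atom, Chain, Residue, Structure


def _ca_structure(positions, bfactors=None):
    residues = []
    for k, pos in enumerate(positions, start=1):
        b = 0.0 if bfactors is None else bfactors[k - 1]
        residues.append(Residue("ALA", k, atoms=[
            Atom("CA", "C", pos, b_factor=b)]))
    return Structure([Chain("A", residues)])


# ---------------------------------------------------------------------------
# weighted contact number

def test_wcn_two_residues():
    s = _ca_structure([[0, 0, 0], [2.0, 0, 0]])
    raw = wcn_raw(s)
    assert raw[1] == pytest.approx(0.25)
    assert raw[2] == pytest.approx(0.25)


def test_wcn_three_collinear():
    s = _ca_structure([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
    raw = wcn_raw(s)
    assert raw[2] == pytest.approx(2 / 9)
    assert raw[1] == pytest.approx(1 / 9 + 1 / 36)
    assert raw[3] == pytest.approx(1 / 9 + 1 / 36)


def test_wcn_single_residue():
    assert wcn_raw(_ca_structure([[0, 0, 0]]))[1] == 0.0


def test_wcn_rigid_motion_invariant(helix15):
    raw = wcn_raw(helix15)
    moved = helix15.with_coords(helix15.coords() @ np.array(
        [[0, 1, 0], [-1, 0, 0], [0, 0, 1.0]]) + 100.0)
    assert wcn_raw(moved) == pytest.approx(raw)


def test_wcn_decreases_when_pair_separates():
    near = wcn_raw(_ca_structure([[0, 0, 0], [2.0, 0, 0], [0, 4.0, 0]]))
    far = wcn_raw(_ca_structure([[0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]]))
    assert far[1] < near[1] and far[2] < near[2]


def test_wcn_profile_is_negated(helix15):
    raw = wcn_raw(helix15)
    col = wcn_profile(helix15)
    assert np.allclose(col.columns["wcn"], [-raw[r] for r in col.residue_ids])


# ---------------------------------------------------------------------------
# solvent-accessible surface area

def test_sasa_isolated_carbon():
    s = _ca_structure([[0, 0, 0]])
    area = atom_sasa(s)[0]
    assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)


def test_sasa_distant_atoms_full_spheres():
    s = _ca_structure([[0, 0, 0], [100.0, 0, 0]])
    areas = atom_sasa(s)
    assert np.allclose(areas, 4 * np.pi * 3.1 ** 2, rtol=1e-6)


def test_sasa_against_fine_quadrature():
    rng = np.random.default_rng(4)
    s = _ca_structure(rng.uniform(0, 4.0, size=(5, 3)))
    coarse = atom_sasa(s, n_points=960)
    fine = atom_sasa(s, n_points=10_000)
    assert abs(coarse.sum() - fine.sum()) / fine.sum() <= 0.02


def test_sasa_quadrature_converges():
    # the pointwise quadrature error oscillates, so compare the mean
    # absolute error over a batch of random clusters
    rng = np.random.default_rng(8)
    errs = {240: [], 960: []}
    for _ in range(12):
        s = _ca_structure(rng.uniform(0, 4.0, size=(5, 3)))
        ref = atom_sasa(s, n_points=20_000).sum()
        for n in errs:
            errs[n].append(abs(atom_sasa(s, n_points=n).sum() - ref))
    assert np.mean(errs[960]) < np.mean(errs[240])


def test_sasa_monotone_under_burial(helix15):
    """Adding atoms can only reduce each residue's accessible area."""
    full = sasa_profile(helix15)
    half = sasa_profile(helix15.subset_residues(set(range(1, 9))))
    for rid, v in zip(half.residue_ids, half.columns["asa"]):
        k = full.residue_ids.index(rid)
        assert full.columns["asa"][k] <= v + 1e-6
    iso = sum(4 * np.pi * (1.7 + 1.4) ** 2 for a in helix15.iter_atoms()
              if a.element == "C")
    assert full.columns["asa"].sum() <= iso * 1.5  # total below isolated sum


def test_sasa_unknown_element_warns():
    s = Structure([Chain("A", [Residue("ALA", 1, atoms=[
        Atom("X1", "X", [0, 0, 0])])])])
    with pytest.warns(UserWarning, match="unknown element"):
        atom_sasa(s)


def test_relative_sasa_bounded(helix15):
    rel = sasa_profile(helix15, relative=True)
    assert np.all(rel.columns["asa"] >= 0)
    assert np.all(rel.columns["asa"] <= 1.6)   # termini may exceed Gly-X-Gly


def test_fibonacci_sphere_uniform():
    pts = _fibonacci_sphere(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


# ---------------------------------------------------------------------------
# B factors

def test_bfactor_mean():
    res = Residue("ALA", 1, atoms=[Atom("N", "N", [0, 0, 0], b_factor=10),
                                   Atom("CA", "C", [1, 0, 0], b_factor=20),
                                   Atom("C", "C", [2, 0, 0], b_factor=30)])
    s = Structure([Chain("A", [res])])
    assert bfactor_profile(s).columns["bfac"][0] == pytest.approx(20.0)


def test_bfactor_uniform_control(helix15):
    s = helix15.copy()
    for a in s.iter_atoms():
        a.b_factor = 20.0
    col = bfactor_profile(s)
    assert np.all(col.columns["bfac"] == 20.0)


def test_bfactor_single_atom():
    s = _ca_structure([[0, 0, 0]], bfactors=[33.0])
    assert bfactor_profile(s).columns["bfac"][0] == 33.0


# ---------------------------------------------------------------------------
# packing/exposure as rigidity proxies

def test_wcn_and_sasa_rank_core_against_tail(helix_tail30):
    """Packed helix-core residues: high WCN, low exposure; tail: opposite."""
    raw = wcn_raw(helix_tail30)
    asa = sasa_profile(helix_tail30)
    asa_by_id = dict(zip(asa.residue_ids, asa.columns["asa"]))
    core = list(range(4, 16))
    tail = list(range(24, 31))
    core_wcn = np.mean([raw[r] for r in core])
    tail_wcn = np.mean([raw[r] for r in tail])
    assert core_wcn > tail_wcn
    assert np.mean([asa_by_id[r] for r in core]) < \
        np.mean([asa_by_id[r] for r in tail])
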