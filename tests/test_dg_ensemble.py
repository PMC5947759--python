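import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mrforge.dg_ensemble import (ConstraintSet, DgParams,
                                 assign_secondary_structure,
                                 extract_constraints, generate_ensemble,
                                 sample_conformation, _chiral_volumes)
from mrforge.structure_io import Atom, Chain, Residue, Structure


def test_sheet_assigned_e(sheet):
    labels = assign_secondary_structure(sheet)
    n = sheet.n_residues // 2
    core = labels[2:n - 2] + labels[n + 2:2 * n - 2]
    assert core and all(l == "E" for l in core)


def test_short_peptide_all_coil():
    from mrforge.fixtures import make_peptide
    assert assign_secondary_structure(make_peptide(2)) == ["C", "C"]


# ---------------------------------------------------------------------------
# constraint extraction against an independent pair-enumeration oracle

def _oracle_tiers(s):
    """Enumerate tiers 1-3 + planar + tier-5 pairs independently.

    Bonds are detected purely geometrically (heavy atoms < 1.8 Angstrom);
    graph distances come from networkx; peptide planes are enumerated
    directly.  Valid for ideal-geometry poly-ALA fixtures.
    """
    coords = s.coords()
    d = squareform(pdist(coords))
    n = len(coords)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in zip(*np.where((d > 0.5) & (d < 1.8))):
        if i < j:
            g.add_edge(int(i), int(j))
    spl = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    tiers = {}
    for i in range(n):
        for j, l in spl[i].items():
            if j > i and 1 <= l <= 3:
                tiers[(i, j)] = l
    # peptide planes CA(i), C(i), O(i), N(i+1), CA(i+1) are rigid (tier 2)
    infos = s.residue_atom_indices()
    for k in range(len(infos) - 1):
        m1 = {a.name: int(q) for a, q in zip(infos[k][1].atoms, infos[k][2])}
        m2 = {a.name: int(q) for a, q in zip(infos[k + 1][1].atoms, infos[k + 1][2])}
        group = [m1["CA"], m1["C"], m1["O"], m2["N"], m2["CA"]]
        for a, b in itertools.combinations(sorted(group), 2):
            if tiers.get((a, b), 9) > 2:
                tiers[(a, b)] = 2
    contacts = {(int(i), int(j)) for i, j in zip(*np.where((d > 0) & (d < 6.0)))
                if i < j}
    return tiers, contacts


def test_constraint_counts_match_enumeration(helix15):
    cs = extract_constraints(helix15)
    got = {t: int(np.sum(cs.tier == t)) for t in range(1, 6)}
    tiers, contacts = _oracle_tiers(helix15)
    want = {t: sum(1 for v in tiers.values() if v == t) for t in (1, 2, 3)}
    assert got[1] == want[1]
    assert got[2] == want[2]
    assert got[3] == want[3]
    # tier 5 = all <6 A contacts not otherwise constrained
    assert got[5] == len(contacts) - len(tiers) - got[4]
    # every tier-4 pair is an N...O hydrogen-bond pair at a sane distance
    names = [a.name for a in helix15.iter_atoms()]
    for k in np.flatnonzero(cs.tier == 4):
        pair = {names[cs.i[k]], names[cs.j[k]]}
        assert pair == {"N", "O"}
    assert got[4] >= 5  # helix core i->i+4 bonds


def test_two_and_three_atom_chains():
    def atom(name, x):
        return Atom(name, "C", [x, 0.0, 0.0])
    two = Structure([Chain("A", [Residue("GLY", 1, atoms=[atom("N", 0.0), atom("CA", 1.45)])])])
    two.chains[0].residues[0].atoms[0].element = "N"
    cs = extract_constraints(two)
    assert len(cs) == 1 and cs.tier[0] == 1
    three = Structure([Chain("A", [Residue("GLY", 1, atoms=[
        Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1.45, 0, 0]),
        Atom("C", "C", [2.0, 1.4, 0])])])])
    cs3 = extract_constraints(three)
    assert sorted(cs3.tier.tolist()) == [1, 1, 2]


def test_clashing_input_rejected(helix15):
    bad = helix15.copy()
    x = bad.coords()
    x[10] = x[30] + 0.3          # two distant-in-sequence atoms on top of each other
    bad.set_coords(x)
    with pytest.raises(ValueError, match="clash"):
        extract_constraints(bad)


def test_constraint_validation():
    from mrforge.dg_ensemble import Constraint
    with pytest.raises(ValueError):
        Constraint(1, 1, 1.0, 2.0, 1)
    with pytest.raises(ValueError):
        Constraint(0, 1, 2.0, 1.0, 1)


# ---------------------------------------------------------------------------
# sampling

def test_zero_sigma_converges_immediately(helix15):
    cs = extract_constraints(helix15)
    conf = sample_conformation(cs, helix15.coords(), seed=5,
                               params=DgParams(start_sigma=0.0))
    assert conf is not None
    assert conf.n_sweeps == 0
    assert np.allclose(conf.positions, helix15.coords())


@pytest.mark.parametrize("seed", range(20))
def test_samples_satisfy_all_constraints(helix15, seed):
    cs = extract_constraints(helix15)
    conf = sample_conformation(cs, helix15.coords(), seed=seed)
    assert conf is not None, f"seed {seed} did not converge"
    assert conf.max_violation <= 0.05
    assert cs.max_violation(conf.positions) <= 0.05
    # chirality preserved at >= 95% of CA centres
    signs = np.sign(_chiral_volumes(conf.positions, cs.chiral_atoms))
    assert np.mean(signs == cs.chiral_signs) >= 0.95


def test_unsatisfiable_constraints_signal_failure():
    # triangle-inequality-violating bounds can never all be satisfied
    cs = ConstraintSet(3, np.array([0, 1, 0]), np.array([1, 2, 2]),
                       np.array([1.0, 1.0, 5.0]), np.array([1.01, 1.01, 5.1]),
                       np.array([1, 1, 5]), np.full(3, 1.7),
                       np.empty((0, 4), dtype=np.int64), np.array([]))
    start = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    assert sample_conformation(cs, start, seed=0,
                               params=DgParams(max_sweeps=50)) is None


def test_sampling_deterministic(helix15):
    cs = extract_constraints(helix15)
    a = sample_conformation(cs, helix15.coords(), seed=42)
    b = sample_conformation(cs, helix15.coords(), seed=42)
    assert np.array_equal(a.positions, b.positions)


def test_generate_ensemble_small(helix15):
    e = generate_ensemble(helix15, n=3, seed=1)
    assert len(e) == 3
    e2 = generate_ensemble(helix15, n=3, seed=1)
    assert np.array_equal(e.member_coords(), e2.member_coords())
    with pytest.raises(ValueError):
        generate_ensemble(helix15, n=0)


def test_loose_regions_fluctuate_more(dg_ensemble30):
    """Residues held only by long-range contacts move more than helix core."""
    e = dg_ensemble30
    ca = e.ca_indices()
    x = e.member_coords()[:, ca]
    from mrforge.ensembling import superpose
    ref = x[0]
    fitted = np.stack([superpose(ref, xi).apply(xi) for xi in x])
    fluct = np.mean(np.sum((fitted - fitted.mean(axis=0)) ** 2, axis=2), axis=0)
    helix_core, tail = fluct[3:17].mean(), fluct[22:].mean()
    assert fluct.min() > 0
    assert tail > helix_core
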