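import numpy as np
import pytest

from mrforge import fixtures
from mrforge.dg_ensemble import Conformation, Ensemble, generate_ensemble


@pytest.fixture(scope="session")
def helix15():
    return fixtures.make_helix(15)


@pytest.fixture(scope="session")
def helix_tail30():
    """20 helical residues followed by a 10-residue extended tail."""
    return fixtures.make_helix_with_tail(20, 10)


@pytest.fixture(scope="session")
def sheet():
    return fixtures.make_sheet(8)


@pytest.fixture(scope="session")
def dg_ensemble30(helix_tail30):
    """A 30-member distance-geometry ensemble of the helix+tail fixture."""
    return generate_ensemble(helix_tail30, n=30, seed=7)


@pytest.fixture(scope="session")
def three_basin_ensemble(helix_tail30):
    """Synthetic ensemble with three conformationally distinct basins.

    The basins differ in the dihedrals of the 10-residue tail (extended /
    bent / helical), so they stay far apart in superposed Cα-RMSD while the
    within-basin spread is small.
    """
    rng = np.random.default_rng(11)
    tails = [fixtures.STRAND_PHI_PSI, (60.0, 60.0), fixtures.HELIX_PHI_PSI]
    members = []
    for size, (tphi, tpsi) in zip((12, 10, 8), tails):
        phis = [fixtures.HELIX_PHI_PSI[0]] * 20 + [tphi] * 10
        psis = [fixtures.HELIX_PHI_PSI[1]] * 20 + [tpsi] * 10
        base = fixtures.make_peptide(30, phis, psis).coords()
        for _ in range(size):
            x = base + rng.normal(0, 0.2, base.shape)
            members.append(Conformation(x, seed=0, n_sweeps=0, max_violation=0.0))
    return Ensemble(helix_tail30, members, n_requested=30, n_discarded=0)


@pytest.fixture()
def helix_pdb(tmp_path, helix_tail30):
    from mrforge.structure_io import write_models
    path = tmp_path / "helix.pdb"
    write_models([helix_tail30], path)
    return path
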