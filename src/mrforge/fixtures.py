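"""Synthetic structure generators used by the test-suite and examples.

Everything downstream consumes only coordinates and topology, so these
fixtures need ideal covalent geometry, not physical realism: peptides are
grown residue by residue from canonical bond lengths/angles and caller-chosen
backbone dihedrals (NeRF construction), and synthetic ensembles displace a
reference structure with per-residue Gaussian noise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dg_ensemble import Conformation, Ensemble, backbone_hbonds
from .structure_io import Atom, Chain, Residue, Structure

# canonical backbone geometry (Engh–Huber-style values, Å and degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_A_X_CA_CB = 110.5

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom d with |cd|=bond, ∠(b,c,d)=angle, τ(a,b,c,d)=torsion."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cβ from the backbone frame, symmetric about N-CA-C, L chirality."""
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    c12 = float(u1 @ u2)
    cos_t = np.cos(np.radians(_A_X_CA_CB))
    alpha = cos_t / (1.0 + c12)
    cross = np.cross(u1, u2)
    beta_sq = (1.0 - alpha ** 2 * (2.0 + 2.0 * c12)) / float(cross @ cross)
    beta = -np.sqrt(max(beta_sq, 0.0))   # sign fixed to L-amino-acid chirality
    direction = alpha * (u1 + u2) + beta * cross
    return ca + _B_CA_CB * direction / np.linalg.norm(direction)


def make_peptide(n_res: int,
                 phi: float | Sequence[float] = HELIX_PHI_PSI[0],
                 psi: float | Sequence[float] = HELIX_PHI_PSI[1],
                 res_name: str = "ALA", chain_id: str = "A") -> Structure:
    """Poly-amino-acid chain with ideal geometry and given backbone dihedrals.

    ``phi``/``psi`` may be scalars or per-residue sequences.  Residues carry
    N, CA, C, O and (except GLY) CB.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))

    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_B_N_CA, 0.0, 0.0])]
    c_pos = [_place(np.array([0.0, -1.0, 0.0]), n_pos[0], ca_pos[0],
                    _B_CA_C, _A_N_CA_C, phis[0] + 180.0)]
    for i in range(1, n_res):
        n_pos.append(_place(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                            _B_C_N, _A_CA_C_N, psis[i - 1]))
        ca_pos.append(_place(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                             _B_N_CA, _A_C_N_CA, 180.0))       # omega trans
        c_pos.append(_place(c_pos[i - 1], n_pos[i], ca_pos[i],
                            _B_CA_C, _A_N_CA_C, phis[i]))

    residues = []
    for i in range(n_res):
        if i < n_res - 1:
            o = _place(n_pos[i + 1], ca_pos[i], c_pos[i],
                       _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = _place(n_pos[i], ca_pos[i], c_pos[i],
                       _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        atoms = [Atom("N", "N", n_pos[i]), Atom("CA", "C", ca_pos[i]),
                 Atom("C", "C", c_pos[i]), Atom("O", "O", o)]
        if res_name != "GLY":
            atoms.append(Atom("CB", "C", _cb_position(n_pos[i], ca_pos[i], c_pos[i])))
        residues.append(Residue(res_name, i + 1, atoms=atoms))
    return Structure([Chain(chain_id, residues)])


def make_helix(n_res: int) -> Structure:
    """Ideal α-helix (φ = −57°, ψ = −47°; ~100° twist, ~1.5 Å rise)."""
    return make_peptide(n_res, *HELIX_PHI_PSI)


def make_strand(n_res: int) -> Structure:
    """Extended β-strand (φ = −139°, ψ = 135°)."""
    return make_peptide(n_res, *STRAND_PHI_PSI)


def make_helix_with_tail(n_helix: int, n_tail: int) -> Structure:
    """A helical segment followed by an extended tail, one chain."""
    n = n_helix + n_tail
    phis = [HELIX_PHI_PSI[0]] * n_helix + [STRAND_PHI_PSI[0]] * n_tail
    psis = [HELIX_PHI_PSI[1]] * n_helix + [STRAND_PHI_PSI[1]] * n_tail
    return make_peptide(n, phis, psis)


def make_sheet(n_res: int = 8, separation_range: tuple[float, float] = (4.2, 5.6),
               shift_range: tuple[float, float] = (-4.0, 4.0)) -> Structure:
    """Two-strand antiparallel β-sheet fixture.

    The second strand is the first flipped 180° about an axis perpendicular
    to the strand direction (reversing its chain direction) and translated
    sideways; flip axis and translation are picked by a grid search that
    maximises the number of inter-strand backbone H-bonds, so the fixture
    contains bridge patterns by construction.
    """
    strand = make_strand(n_res)
    coords = strand.coords()
    centre = coords.mean(axis=0)
    # principal frame: u[:, 0] is the strand axis
    u, _, _ = np.linalg.svd((coords - centre).T @ (coords - centre))
    axis, perp1, perp2 = u[:, 0], u[:, 1], u[:, 2]

    best, best_score = None, -1
    for flip_axis in (perp1, perp2):
        flipped = centre + (coords - centre) @ _rotation_about(flip_axis, np.pi).T
        for sep_dir in (perp1, -perp1, perp2, -perp2):
            for sep in np.arange(*separation_range, 0.1):
                for shift in np.arange(*shift_range, 0.2):
                    cand = flipped + sep * sep_dir + shift * axis
                    two = _two_chain(strand, coords, cand)
                    score = sum(1 for (i, j) in backbone_hbonds(two)
                                if (i < n_res) != (j < n_res))
                    if score > best_score:
                        best, best_score = cand, score
    return _two_chain(strand, coords, best)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _two_chain(template: Structure, coords_a: np.ndarray,
               coords_b: np.ndarray) -> Structure:
    a = template.with_coords(coords_a)
    b = template.with_coords(coords_b)
    chain_b = b.chains[0].copy()
    chain_b.chain_id = "B"
    for res in chain_b.residues:
        res.seq_id += 100
    return Structure([a.chains[0].copy(), chain_b])


def make_perturbed_ensemble(s: Structure, n: int,
                            sigma_profile: dict[int, float] | float,
                            seed: int = 0) -> Ensemble:
    """``n`` copies of ``s`` with residue-wise iid Gaussian displacement.

    ``sigma_profile`` maps residue seq_id to a noise σ in Å (or is one
    scalar for all residues).  Deterministic for a given seed.  This is the
    parameter-recovery harness for variance estimation: downstream code sees
    only coordinates, so Gaussian noise is sufficient even though real
    conformational ensembles are correlated along the chain.
    """
    rng = np.random.default_rng(seed)
    base = s.coords()
    sigma = np.empty(len(base))
    for _, res, idx in s.residue_atom_indices():
        sig = sigma_profile if np.isscalar(sigma_profile) else sigma_profile[res.seq_id]
        if sig < 0:
            raise ValueError(f"negative sigma for residue {res.seq_id}")
        sigma[idx] = sig
    members = [Conformation(base + rng.normal(0.0, 1.0, base.shape) * sigma[:, None],
                            seed=seed, n_sweeps=0, max_violation=0.0)
               for _ in range(n)]
    return Ensemble(s, members, n_requested=n, n_discarded=0)
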