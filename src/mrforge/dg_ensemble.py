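"""Constraint-based distance-geometry ensemble generation.

One sanitized structure is turned into an ensemble of alternative
conformations in the classic two-step scheme — constraint definition, then
coordinate correction:

1. :func:`extract_constraints` reads tiered distance bounds off the input —
   the stronger the interaction, the tighter the allowed band around the
   observed separation (covalent bonds ±0.5% … long-range contacts
   −20%/+25%) — plus a global van der Waals exclusion floor for all
   unconstrained pairs.
2. :func:`sample_conformation` perturbs the coordinates and applies
   pairwise corrections, visiting violated bounds in random order, until
   every bound is satisfied to within a small tolerance.  Non-converging
   runs are discarded and restarted by :func:`generate_ensemble`.

The correction scheme moves both atoms of a violated pair along the pair
axis by half the excess each; its fixed points are exactly the
bound-satisfying coordinate sets.  A chirality guard mirrors the whole
coordinate set if the random start has flipped the majority of Cα centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from ._residues import PLANAR_GROUPS, SIDE_CHAIN_BONDS, vdw_radius
from .structure_io import Structure


@dataclass
class DgParams:
    """Tunable parameters of constraint extraction and sampling."""

    tier_tolerances: tuple[float, float, float, float] = (0.005, 0.015, 0.05, 0.10)
    contact_cutoff: float = 6.0      # Å, tier-5 pair inclusion
    contact_lower_factor: float = 0.8
    contact_upper_factor: float = 1.25
    exclusion_factor: float = 0.8    # × vdW sum, floor for unconstrained pairs
    clash_factor: float = 0.5        # × vdW sum, input rejection threshold
    start_sigma: float = 1.5         # Å, isotropic start perturbation
    tolerance: float = 0.05          # Å, convergence threshold
    max_sweeps: int = 500
    restart_budget_factor: int = 10  # attempts allowed = factor × n


@dataclass(frozen=True)
class Constraint:
    i: int
    j: int
    lower: float
    upper: float
    tier: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("constraint between an atom and itself")
        if not 0 < self.lower <= self.upper:
            raise ValueError(f"invalid bounds [{self.lower}, {self.upper}]")


class ConstraintSet:
    """Tiered distance bounds over one atom set, in flat-array form.

    Besides the bounds themselves this carries what the sampler needs to
    guard stereochemistry: per-atom van der Waals radii for the exclusion
    floor, the Cα chirality centres with their reference signs, and — when
    built from a structure — the reference coordinates plus per-centre
    residue/anchor atom groups used to repair locally mirrored residues.
    """

    def __init__(self, n_atoms: int, i: np.ndarray, j: np.ndarray,
                 lower: np.ndarray, upper: np.ndarray, tier: np.ndarray,
                 radii: np.ndarray,
                 chiral_atoms: np.ndarray, chiral_signs: np.ndarray,
                 reference: np.ndarray | None = None,
                 chiral_fragments: Sequence[tuple[np.ndarray, np.ndarray]] = ()) -> None:
        self.n_atoms = n_atoms
        self.i = np.asarray(i, dtype=np.int64)
        self.j = np.asarray(j, dtype=np.int64)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.tier = np.asarray(tier, dtype=np.int64)
        self.radii = np.asarray(radii, dtype=float)      # per-atom vdW radii
        self.chiral_atoms = chiral_atoms                  # (m, 4): CA, N, C, CB
        self.chiral_signs = chiral_signs
        self.reference = reference
        # per centre: (atom indices of the residue, anchor atom indices)
        self.chiral_fragments = list(chiral_fragments)
        self._pair_keys = frozenset(
            (int(a) * n_atoms + int(b)) for a, b in
            zip(np.minimum(self.i, self.j), np.maximum(self.i, self.j)))

    def __len__(self) -> int:
        return len(self.i)

    @property
    def constraints(self) -> list[Constraint]:
        return [Constraint(int(a), int(b), float(l), float(u), int(t))
                for a, b, l, u, t in
                zip(self.i, self.j, self.lower, self.upper, self.tier)]

    def is_constrained(self, a: int, b: int) -> bool:
        a, b = (a, b) if a < b else (b, a)
        return a * self.n_atoms + b in self._pair_keys

    def max_violation(self, x: np.ndarray) -> float:
        """Largest bound violation (Å) of listed constraints at coords x."""
        d = np.linalg.norm(x[self.i] - x[self.j], axis=1)
        v = np.maximum(self.lower - d, d - self.upper)
        return float(np.max(v, initial=0.0))


@dataclass(eq=False)
class Conformation:
    positions: np.ndarray
    seed: int
    n_sweeps: int
    max_violation: float


@dataclass(eq=False)
class Ensemble:
    """N conformations sharing one atom topology."""

    topology: Structure
    members: list[Conformation]
    n_requested: int
    n_discarded: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def member_coords(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_members, n_atoms, 3)``."""
        return np.stack([m.positions for m in self.members])

    def ca_indices(self) -> np.ndarray:
        idx = []
        for _, res, atom_idx in self.topology.residue_atom_indices():
            for a, k in zip(res.atoms, atom_idx):
                if a.name == "CA":
                    idx.append(k)
        return np.array(idx, dtype=int)

    def residue_ids(self) -> list[int]:
        return [res.seq_id for _, res, idx in self.topology.residue_atom_indices()
                if res.get("CA") is not None]


# ---------------------------------------------------------------------------
# secondary structure (backbone H-bond patterns)

_HB_Q1Q2_F = 0.084 * 332.0   # electrostatic H-bond energy prefactor, kcal/mol
_HB_CUTOFF = -0.5


def _backbone_frames(s: Structure):
    """Per residue: dict of backbone positions or None if incomplete."""
    frames = []
    for _, res in s.iter_residues():
        pos = {}
        for name in ("N", "CA", "C", "O"):
            a = res.get(name)
            if a is not None:
                pos[name] = a.position
        frames.append(pos if len(pos) == 4 else None)
    return frames


def backbone_hbonds(s: Structure) -> set[tuple[int, int]]:
    """Kabsch–Sander-style H-bonds as (acceptor_res, donor_res) index pairs.

    The amide hydrogen is placed 1.0 Å from N opposite the preceding
    carbonyl C=O bond; a bond CO(i)···NH(j) exists when the electrostatic
    energy falls below −0.5 kcal/mol.  Prolines and chain starts donate
    nothing.
    """
    frames = _backbone_frames(s)
    residues = [res for _, res in s.iter_residues()]
    n = len(frames)
    # donor H positions
    hpos: list[np.ndarray | None] = [None] * n
    for j in range(1, n):
        if frames[j] is None or frames[j - 1] is None:
            continue
        if residues[j].name == "PRO":
            continue
        if residues[j].seq_id - residues[j - 1].seq_id != 1:
            continue  # chain break
        co = frames[j - 1]["O"] - frames[j - 1]["C"]
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        hpos[j] = frames[j]["N"] - co / norm * 1.0

    bonds: set[tuple[int, int]] = set()
    for i in range(n):
        if frames[i] is None:
            continue
        c, o = frames[i]["C"], frames[i]["O"]
        for j in range(n):
            if j == i or abs(i - j) < 2 or frames[j] is None or hpos[j] is None:
                continue
            nn, h = frames[j]["N"], hpos[j]
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:
                continue
            e = _HB_Q1Q2_F * (1.0 / r_on
                              + 1.0 / np.linalg.norm(c - h)
                              - 1.0 / np.linalg.norm(o - h)
                              - 1.0 / np.linalg.norm(c - nn))
            if e < _HB_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(s: Structure) -> list[str]:
    """Per-residue labels in {H, E, C} from backbone H-bond patterns.

    H: runs produced by consecutive i→i+4 turns (minimum four residues);
    E: residues in parallel or antiparallel bridge patterns; else C.
    Residues with incomplete backbone are labelled C with a warning.
    """
    frames = _backbone_frames(s)
    n = len(frames)
    if any(f is None for f in frames):
        warnings.warn("residues with missing backbone atoms labelled C")
    labels = ["C"] * n
    hb = backbone_hbonds(s)

    turn4 = [(i, i + 4) in hb for i in range(n)]
    for i in range(1, n):
        if turn4[i - 1] and turn4[i]:
            for k in range(i, min(i + 4, n)):
                labels[k] = "H"

    def bond(a: int, b: int) -> bool:
        return (a, b) in hb

    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = ((bond(i - 1, j) and bond(j, i + 1))
                        or (bond(j - 1, i) and bond(i, j + 1)))
            anti = ((bond(i, j) and bond(j, i))
                    or (bond(i - 1, j + 1) and bond(j - 1, i + 1)))
            if parallel or anti:
                for k in (i, j):
                    if labels[k] != "H":
                        labels[k] = "E"
    return labels


# ---------------------------------------------------------------------------
# constraint extraction

def _bond_list(s: Structure) -> list[tuple[int, int]]:
    """Covalent heavy-atom bonds: residue templates + peptide/SS links."""
    bonds: list[tuple[int, int]] = []
    prev = None  # (chain_id, name->index map, seq_id) of previous residue
    sg_atoms: list[int] = []
    coords = s.coords()
    for chain_id, res, idx in s.residue_atom_indices():
        name_to_idx = {a.name: int(k) for a, k in zip(res.atoms, idx)}
        template = SIDE_CHAIN_BONDS.get(res.name, ())
        pairs = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                 ("C", "OXT")] + list(template)
        for a, b in pairs:
            if a in name_to_idx and b in name_to_idx:
                bonds.append((name_to_idx[a], name_to_idx[b]))
        if "SG" in name_to_idx:
            sg_atoms.append(name_to_idx["SG"])
        if prev is not None:
            p_chain, p_map, p_seq = prev
            if (p_chain == chain_id and res.seq_id - p_seq == 1
                    and "C" in p_map and "N" in name_to_idx):
                d = np.linalg.norm(coords[p_map["C"]] - coords[name_to_idx["N"]])
                if d < 2.5:
                    bonds.append((p_map["C"], name_to_idx["N"]))
        prev = (chain_id, name_to_idx, res.seq_id)
    # disulfides
    for a in range(len(sg_atoms)):
        for b in range(a + 1, len(sg_atoms)):
            if np.linalg.norm(coords[sg_atoms[a]] - coords[sg_atoms[b]]) < 2.5:
                bonds.append((sg_atoms[a], sg_atoms[b]))
    return bonds


def _planar_pairs(s: Structure) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    infos = s.residue_atom_indices()
    maps = [({a.name: int(k) for a, k in zip(res.atoms, idx)}, res, chain_id)
            for chain_id, res, idx in infos]

    def add_group(indices: list[int]) -> None:
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                i, j = sorted((indices[a], indices[b]))
                pairs.add((i, j))

    for name_map, res, _ in maps:
        for group in PLANAR_GROUPS.get(res.name, ()):
            members = [name_map[a] for a in group if a in name_map]
            if len(members) >= 3:
                add_group(members)
    # peptide plane CA(i)-C(i)-O(i)-N(i+1)-CA(i+1)
    for k in range(len(maps) - 1):
        m1, r1, c1 = maps[k]
        m2, r2, c2 = maps[k + 1]
        if c1 != c2 or r2.seq_id - r1.seq_id != 1:
            continue
        members = [m1[a] for a in ("CA", "C", "O") if a in m1]
        members += [m2[a] for a in ("N", "CA") if a in m2]
        if len(members) >= 3:
            add_group(members)
    return pairs


def _chiral_centers(s: Structure):
    """Cα centres (CA, N, C, CB), reference signs and repair fragments."""
    quads, frags = [], []
    coords = s.coords()
    infos = s.residue_atom_indices()
    for k, (_, res, idx) in enumerate(infos):
        name_map = {a.name: int(q) for a, q in zip(res.atoms, idx)}
        if all(n in name_map for n in ("CA", "N", "C", "CB")):
            quads.append([name_map["CA"], name_map["N"], name_map["C"],
                          name_map["CB"]])
            anchors = [int(q) for nb in (k - 1, k + 1) if 0 <= nb < len(infos)
                       for q in infos[nb][2]]
            frags.append((idx.astype(np.int64), np.array(anchors, dtype=np.int64)))
    quads_arr = np.array(quads, dtype=np.int64).reshape(-1, 4)
    signs = np.sign(_chiral_volumes(coords, quads_arr)) if len(quads_arr) else np.array([])
    return quads_arr, signs, frags


def _chiral_volumes(x: np.ndarray, quads: np.ndarray) -> np.ndarray:
    ca, n, c, cb = (x[quads[:, k]] for k in range(4))
    return np.einsum("ij,ij->i", np.cross(n - ca, c - ca), cb - ca)


def extract_constraints(s: Structure, params: DgParams | None = None) -> ConstraintSet:
    """Derive the tiered distance-bound set from a sanitized structure.

    Tiers: 1 covalent bonds; 2 bond-angle (1-3) pairs and rigid/planar
    groups; 3 dihedral (1-4) pairs; 4 backbone H-bond N···O partners inside
    helix/strand elements; 5 all remaining heavy-atom pairs closer than the
    contact cutoff.  Unconstrained pairs are subject to a global exclusion
    floor of ``exclusion_factor ×`` the pair's van der Waals radius sum.
    """
    params = params or DgParams()
    coords = s.coords()
    n = len(coords)
    radii = np.array([vdw_radius(a.element) for a in s.iter_atoms()])

    bonds = _bond_list(s)
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)

    tier_of: dict[tuple[int, int], int] = {}

    def put(a: int, b: int, t: int) -> None:
        key = (a, b) if a < b else (b, a)
        cur = tier_of.get(key)
        if cur is None or t < cur:
            tier_of[key] = t

    for a, b in bonds:
        put(a, b, 1)
    for a in range(n):
        for b in adj[a]:
            for c in adj[b]:
                if c > a:
                    put(a, c, 2)
    # 1-4 pairs
    for a in range(n):
        seen = {a} | adj[a]
        second = set()
        for b in adj[a]:
            second |= adj[b]
        second -= seen
        for c in second:
            for d in adj[c]:
                if d > a and d not in seen and d not in second:
                    put(a, d, 3)

    for a, b in _planar_pairs(s):
        cur = tier_of.get((a, b))
        if cur is None or cur > 2:
            tier_of[(a, b)] = 2

    # tier 4: backbone H-bonds inside H/E elements
    labels = assign_secondary_structure(s)
    name_maps = [{a.name: int(k) for a, k in zip(res.atoms, idx)}
                 for _, res, idx in s.residue_atom_indices()]
    for (acc, don) in backbone_hbonds(s):
        if labels[acc] in "HE" and labels[don] in "HE":
            oi = name_maps[acc].get("O")
            ni = name_maps[don].get("N")
            if oi is not None and ni is not None:
                put(oi, ni, 4)

    # clash check on non-bonded pairs
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(r=float(2 * radii.max() * params.clash_factor)):
        if tier_of.get((min(a, b), max(a, b))) == 1:
            continue
        d = np.linalg.norm(coords[a] - coords[b])
        if d < params.clash_factor * (radii[a] + radii[b]):
            raise ValueError(
                f"input clash: atoms {a} and {b} at {d:.2f} Å "
                f"(< {params.clash_factor} × vdW sum)")

    # tier 5: remaining heavy-atom contacts
    for a, b in tree.query_pairs(r=params.contact_cutoff):
        a, b = (a, b) if a < b else (b, a)
        if (a, b) not in tier_of:
            tier_of[(a, b)] = 5

    ii, jj, lo, hi, tt = [], [], [], [], []
    tol = params.tier_tolerances
    for (a, b), t in sorted(tier_of.items()):
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if t <= 4:
            f = tol[t - 1]
            lo.append(d * (1 - f))
            hi.append(d * (1 + f))
        else:
            vdw = radii[a] + radii[b]
            upper = d * params.contact_upper_factor
            # floor at the vdW sum but never above the observed distance,
            # so the generating structure satisfies its own constraints
            lo.append(min(max(vdw, d * params.contact_lower_factor), d))
            hi.append(upper)
        ii.append(a)
        jj.append(b)
        tt.append(t)

    quads, signs, frags = _chiral_centers(s)
    return ConstraintSet(n, np.array(ii), np.array(jj), np.array(lo),
                         np.array(hi), np.array(tt), radii, quads, signs,
                         reference=coords.copy(), chiral_fragments=frags)


# ---------------------------------------------------------------------------
# sampling

@njit(cache=True)
def _correction_sweep(x, ci, cj, lo, hi, order):  # pragma: no cover - jitted
    for k in order:
        i = ci[k]
        j = cj[k]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d < lo[k]:
            t = lo[k]
        elif d > hi[k]:
            t = hi[k]
        else:
            continue
        if d < 1e-9:
            # coincident atoms: push apart along x
            half = t / 2.0
            x[i, 0] -= half
            x[j, 0] += half
            continue
        f = (d - t) / (2.0 * d)
        x[i, 0] += f * dx
        x[i, 1] += f * dy
        x[i, 2] += f * dz
        x[j, 0] -= f * dx
        x[j, 1] -= f * dy
        x[j, 2] -= f * dz


def _exclusion_violations(cs: ConstraintSet, x: np.ndarray,
                          factor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unconstrained pairs below the exclusion floor, as lower-bound rows."""
    rmax = float(cs.radii.max())
    pairs = cKDTree(x).query_pairs(r=2 * rmax * factor, output_type="ndarray")
    ei, ej, el = [], [], []
    for a, b in pairs:
        a, b = (a, b) if a < b else (b, a)
        floor = factor * (cs.radii[a] + cs.radii[b])
        if np.linalg.norm(x[a] - x[b]) < floor and not cs.is_constrained(a, b):
            ei.append(a)
            ej.append(b)
            el.append(floor)
    return (np.array(ei, dtype=np.int64), np.array(ej, dtype=np.int64),
            np.array(el, dtype=float))


def sample_conformation(cs: ConstraintSet, start: np.ndarray, seed: int,
                        params: DgParams | None = None) -> Conformation | None:
    """One distance-geometry sample; ``None`` signals non-convergence.

    The start coordinates are displaced isotropically (σ =
    ``params.start_sigma`` per atom), then corrected sweep by sweep until the
    largest bound or exclusion violation is at most ``params.tolerance``.
    """
    params = params or DgParams()
    rng = np.random.default_rng(seed)
    x = np.asarray(start, dtype=float).copy()
    if x.shape != (cs.n_atoms, 3):
        raise ValueError("start coordinates do not cover the atom set")
    if params.start_sigma > 0:
        x += rng.normal(0.0, params.start_sigma, size=x.shape)

    big = 1e30
    wrong_age = 0
    for sweep in range(params.max_sweeps + 1):
        ei, ej, el = _exclusion_violations(cs, x, params.exclusion_factor)
        viol = cs.max_violation(x)
        if len(ei):
            d = np.linalg.norm(x[ei] - x[ej], axis=1)
            viol = max(viol, float(np.max(el - d)))
        wrong = _wrong_chiral_centers(x, cs)
        if viol <= params.tolerance and not len(wrong):
            return Conformation(x, seed, sweep, viol)
        if sweep == params.max_sweeps:
            return None

        # mirrored residues are distance-feasible local minima: once the
        # violations are small and a centre stays inverted, rebuild that
        # residue from the reference geometry fitted onto its neighbours
        wrong_age = wrong_age + 1 if len(wrong) else 0
        if (len(wrong) and wrong_age >= 10 and viol <= 10 * params.tolerance
                and cs.reference is not None):
            for k in wrong:
                res_idx, anchors = cs.chiral_fragments[k]
                if len(anchors) < 3:
                    continue
                rot, tr = _kabsch(x[anchors], cs.reference[anchors])
                x[res_idx] = cs.reference[res_idx] @ rot.T + tr
            wrong_age = 0

        ci = np.concatenate([cs.i, ei])
        cj = np.concatenate([cs.j, ej])
        lo = np.concatenate([cs.lower, el])
        hi = np.concatenate([cs.upper, np.full(len(ei), big)])
        order = rng.permutation(len(ci))
        _correction_sweep(x, ci, cj, lo, hi, order)
    return None


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation/translation fitting b onto a (local helper)."""
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb_).T @ (a - ca_)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, ca_ - rot @ cb_


def _wrong_chiral_centers(x: np.ndarray, cs: ConstraintSet) -> np.ndarray:
    """Indices of inverted Cα centres, after un-mirroring the whole set.

    A random start can land in the global mirror image (distances are
    reflection-invariant); if the majority of centres are inverted the
    entire coordinate set is reflected in place first.
    """
    if not len(cs.chiral_atoms):
        return np.empty(0, dtype=int)
    signs = np.sign(_chiral_volumes(x, cs.chiral_atoms))
    wrong = signs != cs.chiral_signs
    if wrong.sum() > len(signs) / 2:
        x[:, 0] *= -1.0
        wrong = -signs != cs.chiral_signs
    return np.flatnonzero(wrong)


def generate_ensemble(s: Structure, n: int = 500, seed: int = 0,
                      params: DgParams | None = None) -> Ensemble:
    """Generate exactly ``n`` accepted conformations (default 500).

    Child seeds are ``seed + attempt_index``, so results are deterministic
    for a given (seed, n).  Non-converging attempts are discarded; the run
    aborts if ``restart_budget_factor × n`` attempts are exhausted.
    """
    params = params or DgParams()
    if n < 1:
        raise ValueError("n must be >= 1")
    cs = extract_constraints(s, params)
    start = s.coords()
    members: list[Conformation] = []
    attempts = 0
    budget = params.restart_budget_factor * n
    while len(members) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"restart budget exhausted: {attempts} attempts for {len(members)}/{n} "
                "accepted conformations")
        conf = sample_conformation(cs, start, seed + attempts, params)
        attempts += 1
        if conf is not None:
            members.append(conf)
    return Ensemble(s, members, n_requested=n, n_discarded=attempts - n)
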