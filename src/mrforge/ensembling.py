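"""Ensemble clustering, per-residue variance and fixed-radius subclusters.

The three stages between raw conformational ensembles and search models:

* greedy neighbour-count clustering on the pairwise Cα-RMSD matrix (the
  member with most neighbours within a cutoff seeds each cluster), with the
  cutoff auto-tuned so the top cluster is neither trivial nor all-engulfing;
* iterative reweighted superposition of a cluster to its evolving mean,
  down-weighting variable residues, yielding the per-residue variance
  profile that drives truncation;
* subclusters: members within a fixed Cα-RMSD radius of the cluster
  centroid, ranked by RMSD and capped, which become the coordinate sets of
  one ensemble search model.

All RMSDs and variances are Cα-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dg_ensemble import Ensemble


@dataclass
class SuperpositionResult:
    """Least-squares fit of coordinate set b onto a: ``a ≈ R·b + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ClusterSet:
    clusters: list[list[int]]          # member indices, descending size
    centroid_indices: list[int]
    cutoff_used: float

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class VarianceProfile:
    """Per-residue Cα variance (Å²) keyed by author residue number."""

    values: dict[int, float]
    n_members: int

    def as_scores(self) -> dict[int, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------

def superpose(a: np.ndarray, b: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted Kabsch superposition of ``b`` onto ``a``.

    Returns the proper rotation and translation minimising the weighted
    RMSD.  Degenerate (collinear or single-point) sets fall back to a
    translation-only fit and are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 3:
        raise ValueError("superpose needs two equal (n>=3, 3) coordinate sets")
    if weights is None:
        w = np.ones(len(a))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")
    wn = w / w.sum()
    ca = wn @ a
    cb = wn @ b
    am = a - ca
    bm = b - cb

    h = (bm * wn[:, None]).T @ am
    u, s, vt = np.linalg.svd(h)
    # collinearity: fewer than two significant singular values
    if np.sum(s > max(s[0], 1e-12) * 1e-8) < 2:
        t = ca - cb
        rmsd = float(np.sqrt(np.sum(wn * np.sum((a - (b + t)) ** 2, axis=1))))
        return SuperpositionResult(np.eye(3), t, rmsd, degenerate=True)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca - r @ cb
    fitted = b @ r.T + t
    rmsd = float(np.sqrt(np.sum(wn * np.sum((a - fitted) ** 2, axis=1))))
    return SuperpositionResult(r, t, rmsd)


def pairwise_ca_rmsd(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of optimal-superposition RMSDs, batched Kabsch.

    ``coords`` has shape ``(n_members, n_atoms, 3)``.
    """
    x = coords - coords.mean(axis=1, keepdims=True)
    m = x.shape[1]
    g = np.einsum("pij,pij->p", x, x)                       # squared norms
    h = np.einsum("pmi,qmj->pqij", x, x)                    # cross-covariances
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    d = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
    sq = (g[:, None] + g[None, :] - 2.0 * d) / m
    out = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


def cluster(e: Ensemble, initial_cutoff: float = 1.5,
            cutoff_range: tuple[float, float] = (0.5, 8.0),
            top_fraction_band: tuple[float, float] = (0.15, 0.85),
            max_clusters: int = 3) -> ClusterSet:
    """Greedy neighbour-count clustering of ensemble members.

    The RMSD cutoff starts at ``initial_cutoff`` and is scaled within
    ``cutoff_range`` until cluster 1 holds a fraction of the members inside
    ``top_fraction_band``; members of each cluster are removed before the
    next is seeded.  At most ``max_clusters`` clusters are returned, ordered
    by size (ties by lowest centroid index).
    """
    n = len(e)
    if n < 2:
        return ClusterSet([list(range(n))], [0] * min(n, 1), initial_cutoff)
    ca = e.ca_indices()
    dmat = pairwise_ca_rmsd(e.member_coords()[:, ca])

    lo_f, hi_f = top_fraction_band
    lo_c, hi_c = cutoff_range
    cutoff = float(np.clip(initial_cutoff, lo_c, hi_c))
    for _ in range(60):
        frac = _top_cluster_size(dmat, cutoff) / n
        if frac > hi_f and cutoff > lo_c:
            cutoff = max(cutoff / 1.25, lo_c)
        elif frac < lo_f and cutoff < hi_c:
            cutoff = min(cutoff * 1.25, hi_c)
        else:
            break

    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    centroids: list[int] = []
    within = dmat <= cutoff
    while remaining.any() and len(clusters) < max_clusters:
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))           # argmax ties -> lowest index
        members = np.flatnonzero(within[seed] & remaining)
        clusters.append(sorted(int(k) for k in members))
        centroids.append(seed)
        remaining[members] = False

    order = sorted(range(len(clusters)),
                   key=lambda k: (-len(clusters[k]), centroids[k]))
    return ClusterSet([clusters[k] for k in order],
                      [centroids[k] for k in order], cutoff)


def _top_cluster_size(dmat: np.ndarray, cutoff: float) -> int:
    return int((dmat <= cutoff).sum(axis=1).max())


def variance_profile(e: Ensemble, members: list[int] | None = None,
                     eps: float = 1e-6, max_iter: int = 50,
                     rel_tol: float = 1e-4) -> VarianceProfile:
    """Per-residue Cα variance from iterative reweighted superposition.

    Members are superposed onto the evolving mean structure with residue
    weights 1/(variance + eps), so rigid residues dominate the frame and
    mobile ones do not smear it; the variance of a residue is its mean
    squared Cα deviation from the mean structure.  Invariant under
    rigid-body motion of any member.
    """
    idx = members if members is not None else list(range(len(e)))
    if len(idx) < 2:
        raise ValueError("variance profile needs at least 2 members")
    ca = e.ca_indices()
    x = e.member_coords()[idx][:, ca]           # (k, m, 3)
    k, m, _ = x.shape

    # initial frame: unweighted fit to the first member
    cur = np.stack([superpose(x[0], xi).apply(xi) for xi in x])
    mean = cur.mean(axis=0)
    var = np.mean(np.sum((cur - mean) ** 2, axis=2), axis=0)
    for _ in range(max_iter):
        w = 1.0 / (var + eps)
        cur = np.stack([superpose(mean, xi, w).apply(xi) for xi in x])
        mean = cur.mean(axis=0)
        new_var = np.mean(np.sum((cur - mean) ** 2, axis=2), axis=0)
        change = np.max(np.abs(new_var - var) / np.maximum(new_var, eps))
        var = new_var
        if change < rel_tol:
            break
    rids = e.residue_ids()
    return VarianceProfile({rid: float(v) for rid, v in zip(rids, var)},
                           n_members=k)


def subcluster(e: Ensemble, members: list[int], centroid: int,
               radius: float, cap: int = 30) -> list[int]:
    """Members within Cα-RMSD ``radius`` of the centroid, nearest first.

    The centroid itself is always included; the list is truncated to
    ``cap`` entries.
    """
    ca = e.ca_indices()
    coords = e.member_coords()[:, ca]
    ref = coords[centroid]
    scored = []
    for k in members:
        r = 0.0 if k == centroid else superpose(ref, coords[k]).rmsd
        scored.append((r, k))
    scored.sort()
    picked = [k for r, k in scored if r <= radius or k == centroid]
    if centroid not in picked:
        picked.insert(0, centroid)
    return picked[:cap]
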