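"""Graded truncation of ensembles into pools of search models.

A per-residue score (ensemble variance, or any external profile) defines a
fixed removal order: the highest-scoring residues go first.  Twenty
truncation levels retain k/20 of the residues (k = 20..1, floor, minimum
one residue), so a 100-residue chain yields models of 100, 95, 90, … 5
residues.  Each truncated ensemble is emitted at three subclustering radii
and under three side-chain treatments (all atoms kept / the reliable
rotamer set kept / stripped to poly-alanine), giving 20 × 3 × 3 = 180
search models per cluster and 540 when three clusters are used.  Identical
models arising from different radii are kept by default so the pool-size
law holds exactly; ``dedupe`` removes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._residues import POLYALA_ATOMS, RELIABLE_SIDE_CHAINS
from .dg_ensemble import Ensemble
from .ensembling import ClusterSet, subcluster, superpose, variance_profile
from .structure_io import Structure

SIDE_CHAIN_MODES = ("allatom", "reliable", "polyala")
DEFAULT_RADII = (1.0, 2.0, 3.0)
N_LEVELS = 20


@dataclass
class TruncationLevel:
    fraction: float
    n_keep: int
    kept_ids: tuple[int, ...] | None = None


@dataclass(eq=False)
class SearchModel:
    """One truncated, side-chain-processed (ensemble) search model."""

    structure: Structure            # member coordinate sets as MODEL blocks
    n_residues: int
    side_chain_mode: str
    subcluster_radius: float | None
    cluster_index: int | None
    label: str
    member_indices: tuple[int, ...] = ()

    @property
    def n_members(self) -> int:
        return self.structure.n_models


def truncation_ladder(n_residues: int, n_levels: int = N_LEVELS) -> list[TruncationLevel]:
    """Descending retained-size ladder at fractions k/n_levels, k = n..1.

    Sizes are floored and clamped to at least one residue; levels that
    collapse onto the same size are merged (first, i.e. largest-fraction,
    occurrence kept).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    levels: list[TruncationLevel] = []
    seen: set[int] = set()
    for k in range(n_levels, 0, -1):
        frac = k / n_levels
        n_keep = max(1, math.floor(n_residues * frac))
        if n_keep not in seen:
            seen.add(n_keep)
            levels.append(TruncationLevel(frac, n_keep))
    return levels


def select_residues(profile: Mapping[int, float], n_keep: int) -> tuple[int, ...]:
    """The ``n_keep`` residues with the lowest scores (highest removed first).

    Ties break towards the lower residue number.  Only the rank order of
    the profile matters.
    """
    if n_keep > len(profile):
        raise ValueError(f"n_keep={n_keep} exceeds {len(profile)} scored residues")
    ranked = sorted(profile, key=lambda rid: (profile[rid], rid))
    return tuple(sorted(ranked[:n_keep]))


def apply_side_chains(model: Structure, mode: str) -> Structure:
    """Apply one side-chain treatment to a (possibly multi-model) structure.

    ``allatom`` keeps everything; ``polyala`` strips to N, CA, C, O, CB and
    renames non-glycine residues to ALA; ``reliable`` keeps side chains only
    for residue types with few well-occupied rotamers and strips the rest
    to the poly-alanine atom set (names preserved).
    """
    if mode == "allatom":
        return model.copy()
    if mode not in SIDE_CHAIN_MODES:
        raise ValueError(f"unknown side-chain mode {mode!r}")
    keep = []
    for _, res in model.iter_residues():
        full = mode == "reliable" and res.name in RELIABLE_SIDE_CHAINS
        keep.extend(True if full else (a.name in POLYALA_ATOMS) for a in res.atoms)
    out = model.subset_atoms(keep)
    if mode == "polyala":
        for _, res in out.iter_residues():
            if res.name != "GLY":
                res.name = "ALA"
    return out


def build_search_models(e: Ensemble, clusters: ClusterSet,
                        n_clusters_used: int = 1,
                        radii: Sequence[float] = DEFAULT_RADII,
                        modes: Sequence[str] = SIDE_CHAIN_MODES,
                        cap: int = 30, n_levels: int = N_LEVELS,
                        dedupe: bool = False) -> list[SearchModel]:
    """The full pool: levels × radii × side-chain modes per used cluster.

    For each used cluster the variance profile of its members fixes the
    residue removal order; each subcluster's members are superposed onto
    the cluster centroid (Cα fit applied to all atoms) before truncation.
    A cluster too small to subcluster still emits models built from its
    centroid alone.
    """
    pool: list[SearchModel] = []
    seen_keys: set[tuple] = set()
    used = clusters.clusters[:n_clusters_used]
    ca = e.ca_indices()
    all_coords = e.member_coords()

    for c_rank, members in enumerate(used, start=1):
        centroid = clusters.centroid_indices[c_rank - 1]
        if len(members) >= 2:
            profile = variance_profile(e, members).as_scores()
        else:
            # single-member cluster: flat profile, removal order by seq_id
            profile = {rid: 0.0 for rid in e.residue_ids()}
        ladder = truncation_ladder(len(profile), n_levels)
        for level in ladder:
            level.kept_ids = select_residues(profile, level.n_keep)

        for radius in radii:
            sub = subcluster(e, members, centroid, radius, cap)
            ref = all_coords[centroid][ca]
            fitted = []
            for k in sub:
                fit = superpose(ref, all_coords[k][ca])
                fitted.append(fit.apply(all_coords[k]))
            base = e.topology.with_coords(fitted[0])
            base.alt_model_coords = [c.copy() for c in fitted[1:]]

            for level in ladder:
                truncated = base.subset_residues(level.kept_ids)
                for mode in modes:
                    model = apply_side_chains(truncated, mode)
                    label = (f"c{c_rank}_t{round(level.fraction * 100)}"
                             f"_r{radius:g}_{mode}")
                    if dedupe:
                        key = (c_rank, tuple(sub), level.kept_ids, mode)
                        if key in seen_keys:
                            continue
                        seen_keys.add(key)
                    pool.append(SearchModel(model, level.n_keep, mode,
                                            float(radius), c_rank, label,
                                            tuple(sub)))
    return pool
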