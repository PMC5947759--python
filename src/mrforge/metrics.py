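"""Built-in per-residue score generators.

Packing and rigidity correlate with evolutionary conservation, so cheap
structure-derived profiles can stand in for conservation when ranking
residues for truncation:

* weighted contact number (WCN): Σ 1/d² over Cα pairs — a packing density;
* solvent-accessible surface area (Shrake–Rupley);
* residue-averaged crystallographic B factor;
* ensemble variance (via :func:`mrforge.ensembling.variance_profile`).

All columns obey the truncation contract "higher score = removed earlier":
WCN is therefore emitted negated (well-packed residues are kept longest),
while ASA, B factor and variance are already oriented correctly.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from ._residues import vdw_radius
from .dg_ensemble import Ensemble
from .ensembling import variance_profile
from .score_mode import ScoreTable
from .structure_io import Structure

DEFAULT_PROBE = 1.4      # Å, water probe
DEFAULT_N_POINTS = 960   # Fibonacci-sphere quadrature points per atom

# Theoretical maximum ASA per residue type (Gly-X-Gly, Å²; Tien et al. scale)
_MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _residue_table(s: Structure, values: dict[int, float], name: str) -> ScoreTable:
    ids = tuple(values)
    return ScoreTable(ids, {name: np.array([values[r] for r in ids])})


def wcn_raw(s: Structure, center: Literal["CA", "centroid"] = "CA") -> dict[int, float]:
    """Unnormalised weighted contact number Σ_j 1/d(i,j)² per residue.

    ``center`` picks the per-residue point: Cα or the side-chain centroid
    (falling back to Cα for glycine).  Residues lacking the centre atom are
    excluded with a warning.
    """
    points, ids = [], []
    for _, res in s.iter_residues():
        if center == "CA":
            a = res.get("CA")
            pos = a.position if a is not None else None
        else:
            side = [a.position for a in res.atoms
                    if a.name not in ("N", "CA", "C", "O")]
            if side:
                pos = np.mean(side, axis=0)
            else:
                a = res.get("CA")
                pos = a.position if a is not None else None
        if pos is None:
            warnings.warn(f"residue {res.seq_id} lacks a {center} point; excluded")
            continue
        points.append(pos)
        ids.append(res.seq_id)
    x = np.asarray(points)
    out: dict[int, float] = {}
    for k, rid in enumerate(ids):
        d2 = np.sum((x - x[k]) ** 2, axis=1)
        d2[k] = np.inf
        out[rid] = float(np.sum(1.0 / d2))
    return out


def wcn_profile(s: Structure, center: Literal["CA", "centroid"] = "CA") -> ScoreTable:
    """Negated WCN as a truncation score column named ``wcn``.

    High contact number means a well-packed residue that should be kept, so
    the emitted score is −WCN to satisfy "higher = removed earlier".
    """
    raw = wcn_raw(s, center)
    return _residue_table(s, {rid: -v for rid, v in raw.items()}, "wcn")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def atom_sasa(s: Structure, probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Shrake–Rupley solvent-accessible area per atom, Å².

    Quasi-uniform points on each atom's probe-expanded sphere are tested
    against every neighbouring expanded sphere; the accessible fraction
    scales the sphere area.  Unknown elements fall back to a 1.8 Å radius
    with a warning.
    """
    atoms = list(s.iter_atoms())
    known = {"C", "N", "O", "S"}
    for a in atoms:
        if a.element.upper() not in known:
            warnings.warn(f"unknown element {a.element!r}: using default vdW radius")
    radii = np.array([vdw_radius(a.element) for a in atoms]) + probe
    x = s.coords()
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(x)
    out = np.empty(len(atoms))
    rmax = radii.max()
    for i in range(len(atoms)):
        pts = x[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(x[i], radii[i] + rmax)
                      if j != i and np.linalg.norm(x[j] - x[i]) < radii[i] + radii[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= np.sum((pts - x[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def sasa_profile(s: Structure, probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 relative: bool = False) -> ScoreTable:
    """Residue ASA (sum over atoms) as a score column named ``asa``.

    With ``relative`` the total is divided by the residue type's
    Gly-X-Gly maximum, giving relative solvent accessibility.
    """
    per_atom = atom_sasa(s, probe, n_points)
    values: dict[int, float] = {}
    for _, res, idx in s.residue_atom_indices():
        total = float(per_atom[idx].sum())
        if relative:
            total /= _MAX_ASA.get(res.name, np.mean(list(_MAX_ASA.values())))
        values[res.seq_id] = total
    return _residue_table(s, values, "asa")


def bfactor_profile(s: Structure) -> ScoreTable:
    """Arithmetic mean heavy-atom B factor per residue, column ``bfac``."""
    values = {res.seq_id: float(np.mean([a.b_factor for a in res.atoms]))
              for _, res in s.iter_residues()}
    return _residue_table(s, values, "bfac")


def ensemble_variance_profile(e: Ensemble) -> ScoreTable:
    """Per-residue Cα variance of an ensemble, column ``ensvar``."""
    prof = variance_profile(e)
    return ScoreTable(tuple(prof.values),
                      {"ensvar": np.array(list(prof.values.values()))})
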