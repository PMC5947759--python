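"""Single-structure truncation driven by per-residue score files.

Instead of an ensemble, one model is truncated progressively according to a
plain-text score table: column 1 holds author residue numbers, columns 2..n
hold named scores (header line gives the titles), and the residues removed
first are those with the highest values.  Each score column independently
yields 20 truncation levels × 3 side-chain treatments = 60 search models;
all columns pool together.

Score semantics are fixed as "higher = removed earlier", which suits
flexibility/exposure metrics directly; conservation-style scores (higher =
keep) must be negated by the user before input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Structure
from .truncation_factory import (SIDE_CHAIN_MODES, N_LEVELS, SearchModel,
                                 apply_side_chains, select_residues,
                                 truncation_ladder)


@dataclass
class ScoreTable:
    """Residue numbers plus one or more named score columns."""

    residue_ids: tuple[int, ...]
    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("duplicate residue ids in score table")
        if not self.columns:
            raise ValueError("score table needs at least one score column")
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (len(self.residue_ids),):
                raise ValueError(f"column {name!r} length mismatch")
            self.columns[name] = col

    def profile(self, name: str) -> dict[int, float]:
        return dict(zip(self.residue_ids, (float(v) for v in self.columns[name])))

    def merged(self, other: "ScoreTable") -> "ScoreTable":
        if other.residue_ids != self.residue_ids:
            raise ValueError("cannot merge score tables over different residues")
        cols = dict(self.columns)
        cols.update(other.columns)
        return ScoreTable(self.residue_ids, cols)


def parse_score_file(path: str | Path) -> ScoreTable:
    """Parse a whitespace- or comma-delimited score table with a header line.

    The delimiter is auto-detected from the header.  Errors carry the
    1-based line number of the offending row.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()]
    rows = [(k + 1, ln.strip()) for k, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header line and at least one data row")

    header_no, header = rows[0]
    sep = "," if "," in header else None
    titles = [t.strip() for t in header.split(sep)]
    if len(titles) < 2:
        raise ValueError(f"{path}:{header_no}: header must name residue and score columns")
    col_names = titles[1:]
    if len(set(col_names)) != len(col_names):
        raise ValueError(f"{path}:{header_no}: duplicate column titles")

    ids: list[int] = []
    data: list[list[float]] = []
    for line_no, row in rows[1:]:
        cells = [c.strip() for c in row.split(sep)]
        if len(cells) != len(titles):
            raise ValueError(f"{path}:{line_no}: expected {len(titles)} columns, "
                             f"got {len(cells)}")
        try:
            rid = int(float(cells[0]))
        except ValueError:
            raise ValueError(f"{path}:{line_no}: residue number {cells[0]!r} "
                             "is not numeric") from None
        try:
            vals = [float(c) for c in cells[1:]]
        except ValueError:
            raise ValueError(f"{path}:{line_no}: non-numeric score value") from None
        if rid in ids:
            raise ValueError(f"{path}:{line_no}: duplicate residue id {rid}")
        ids.append(rid)
        data.append(vals)

    arr = np.array(data, dtype=float)
    return ScoreTable(tuple(ids), {name: arr[:, k].copy()
                                   for k, name in enumerate(col_names)})


def write_score_file(table: ScoreTable, path: str | Path) -> Path:
    """Write a table in exactly the format :func:`parse_score_file` reads."""
    path = Path(path)
    names = list(table.columns)
    lines = ["res " + " ".join(names)]
    for k, rid in enumerate(table.residue_ids):
        lines.append(f"{rid} " + " ".join(f"{table.columns[n][k]:.6g}" for n in names))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def truncate_single_model(s: Structure, table: ScoreTable,
                          modes: Sequence[str] = SIDE_CHAIN_MODES,
                          n_levels: int = N_LEVELS) -> list[SearchModel]:
    """Truncate one model per score column; pool everything together.

    The score table must cover exactly the residues of the structure —
    silent imputation of missing scores would corrupt the removal order, so
    any mismatch is an error.
    """
    struct_ids = [res.seq_id for _, res in s.iter_residues()]
    extra = set(table.residue_ids) - set(struct_ids)
    if extra:
        raise ValueError(f"score rows for residues absent from the structure: "
                         f"{sorted(extra)[:10]}")
    missing = set(struct_ids) - set(table.residue_ids)
    if missing:
        raise ValueError(f"structure residues missing from the score table: "
                         f"{sorted(missing)[:10]}")

    pool: list[SearchModel] = []
    for name in table.columns:
        profile = table.profile(name)
        for level in truncation_ladder(len(profile), n_levels):
            kept = select_residues(profile, level.n_keep)
            truncated = s.subset_residues(kept)
            for mode in modes:
                model = apply_side_chains(truncated, mode)
                label = f"s_{name}_t{round(level.fraction * 100)}_{mode}"
                pool.append(SearchModel(model, level.n_keep, mode, None, None,
                                        label))
    return pool
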