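"""Position-pair heatmaps, the 18-of-20 pattern rule, and the HM score.

Motifs sharing a residue pair at two of the three variable positions form
20-member groups; the mean EF of each group fills one cell of a 20x20
heatmap, one heatmap per ordered pair (a1 x a2, a1 x X, a2 x X).  Each
heatmap partitions the 8,000-motif space, so the unweighted mean of its
400 cells equals the grand-mean EF.

A residue shows a significant contextual pattern when at least 18 of its
20 cells lie strictly beyond a cutoff of grand_mean +/- z * SD, where the
SD is taken over the 20 row means (for row patterns) or the 20 column
means (for column patterns); z defaults to 1.96 (a 95% interval).

The HM score of a motif is the sum of its three heatmap cells — three
context-averaged EFs of 20 motifs each — and serves as a prenylation
predictor (positive call above 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EFTable
from .motifs import AMINO_ACIDS, enumerate_cxxx

#: Ordered position pairs, in canonical order.
PAIRS: tuple[tuple[str, str], ...] = (("a1", "a2"), ("a1", "x"), ("a2", "x"))

_AXIS_OF = {"a1": 0, "a2": 1, "x": 2}


@dataclass
class HeatmapMatrix:
    """20x20 mean-EF matrix for one ordered position pair.

    ``cells[r, c]`` is the mean EF of the 20 motifs with residue
    ``AMINO_ACIDS[r]`` at ``pair[0]`` and ``AMINO_ACIDS[c]`` at ``pair[1]``.
    """

    pair: tuple[str, str]
    cells: np.ndarray
    grand_mean: float

    def cell(self, res_row: str, res_col: str) -> float:
        return float(self.cells[AMINO_ACIDS.index(res_row),
                                AMINO_ACIDS.index(res_col)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(AMINO_ACIDS),
                            columns=list(AMINO_ACIDS))

    def to_long(self) -> pd.DataFrame:
        rows, cols = np.meshgrid(range(20), range(20), indexing="ij")
        return pd.DataFrame({
            f"{self.pair[0]}_res": [AMINO_ACIDS[i] for i in rows.ravel()],
            f"{self.pair[1]}_res": [AMINO_ACIDS[j] for j in cols.ravel()],
            "mean_ef": self.cells.ravel(),
        })


@dataclass
class PatternResult:
    """One significant contextual pattern call."""

    position: str           # position of the flagged residue
    residue: str
    context: tuple[str, str]  # the heatmap (ordered pair) it was found in
    direction: str          # "positive" or "restrictive"
    n_beyond_cutoff: int

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "residue": self.residue,
            "context": list(self.context),
            "direction": self.direction,
            "n_beyond_cutoff": self.n_beyond_cutoff,
        }


def _ef_cube(table: EFTable) -> np.ndarray:
    """EF values as a (20, 20, 20) array indexed by (a1, a2, x).

    Relies on enumerate_cxxx order; falls back to an explicit reindex for
    externally loaded tables in any row order.
    """
    table.require_full()
    df = table.df
    if list(df["motif"]) == enumerate_cxxx():
        ef = df["ef"].to_numpy(dtype=float)
    else:
        ef = df.set_index("motif")["ef"].reindex(enumerate_cxxx()).to_numpy(
            dtype=float)
    return ef.reshape(20, 20, 20)


def build_heatmap(table: EFTable, pair: tuple[str, str]) -> HeatmapMatrix:
    """Mean-EF heatmap for one ordered position pair over a full table."""
    if tuple(pair) not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}, got {pair}")
    cube = _ef_cube(table)
    other_axis = ({0, 1, 2} - {_AXIS_OF[pair[0]], _AXIS_OF[pair[1]]}).pop()
    cells = cube.mean(axis=other_axis)
    if _AXIS_OF[pair[0]] > _AXIS_OF[pair[1]]:  # keep pair[0] on rows
        cells = cells.T
    return HeatmapMatrix(pair=tuple(pair), cells=cells,
                         grand_mean=float(cube.mean()))


def build_all_heatmaps(table: EFTable) -> dict[tuple[str, str], HeatmapMatrix]:
    return {pair: build_heatmap(table, pair) for pair in PAIRS}


def detect_patterns(
    hm: HeatmapMatrix,
    z: float = 1.96,
    min_members: int = 18,
) -> list[PatternResult]:
    """Flag residues whose 20-cell row/column lies beyond the CI cutoff.

    Rows and columns are analyzed separately: the cutoff for rows uses the
    SD over the 20 row means, for columns the SD over the 20 column means
    (population SD, around the grand mean).  Cells exactly on a cutoff do
    not count ("above or below" is strict).
    """
    results: list[PatternResult] = []
    for axis, position in ((1, hm.pair[0]), (0, hm.pair[1])):
        # axis=1 -> row means -> patterns for the row position
        line_means = hm.cells.mean(axis=axis)
        sd = float(line_means.std(ddof=0))
        high = hm.grand_mean + z * sd
        low = hm.grand_mean - z * sd
        lines = hm.cells if axis == 1 else hm.cells.T
        for i, residue in enumerate(AMINO_ACIDS):
            n_above = int((lines[i] > high).sum())
            n_below = int((lines[i] < low).sum())
            if n_above >= min_members:
                results.append(PatternResult(
                    position, residue, hm.pair, "positive", n_above))
            if n_below >= min_members:
                results.append(PatternResult(
                    position, residue, hm.pair, "restrictive", n_below))
    return results


def detect_all_patterns(
    heatmaps: dict[tuple[str, str], HeatmapMatrix] | Sequence[HeatmapMatrix],
    z: float = 1.96,
    min_members: int = 18,
) -> list[PatternResult]:
    hms = heatmaps.values() if isinstance(heatmaps, dict) else heatmaps
    out: list[PatternResult] = []
    for hm in hms:
        out.extend(detect_patterns(hm, z=z, min_members=min_members))
    return out


def hm_score(motif: str,
             heatmaps: dict[tuple[str, str], HeatmapMatrix]) -> float:
    """Sum of the three heatmap cells indexed by the motif's residue pairs."""
    a1, a2, x = motif[1], motif[2], motif[3]
    return (heatmaps[("a1", "a2")].cell(a1, a2)
            + heatmaps[("a1", "x")].cell(a1, x)
            + heatmaps[("a2", "x")].cell(a2, x))


def hm_score_all(table: EFTable) -> pd.DataFrame:
    """HM components and score for all 8,000 motifs.

    Columns: motif, hm_a1a2, hm_a1x, hm_a2x, hm_score.
    """
    heatmaps = build_all_heatmaps(table)
    idx = np.arange(8000)
    i1, rem = divmod(idx, 400)
    i2, i3 = divmod(rem, 20)
    comp12 = heatmaps[("a1", "a2")].cells[i1, i2]
    comp13 = heatmaps[("a1", "x")].cells[i1, i3]
    comp23 = heatmaps[("a2", "x")].cells[i2, i3]
    return pd.DataFrame({
        "motif": enumerate_cxxx(),
        "hm_a1a2": comp12,
        "hm_a1x": comp13,
        "hm_a2x": comp23,
        "hm_score": comp12 + comp13 + comp23,
    })


def write_heatmap(hm: HeatmapMatrix, path: str | Path,
                  long_format: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pair={hm.pair[0]}x{hm.pair[1]}\n")
        fh.write(f"# grand_mean={hm.grand_mean!r}\n")
        if long_format:
            hm.to_long().to_csv(fh, sep="\t", index=False)
        else:
            hm.to_frame().to_csv(fh, sep="\t", index_label="")


def write_pattern_report(
    patterns: Sequence[PatternResult], path: str | Path,
    z: float = 1.96, min_members: int = 18,
) -> None:
    with open(path, "w") as fh:
        json.dump({
            "cutoff_rule": {
                "z": z,
                "min_members": min_members,
                "sd_over": "row/column means (population SD)",
                "inequality": "strict",
            },
            "patterns": [p.to_dict() for p in patterns],
        }, fh, indent=2)
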