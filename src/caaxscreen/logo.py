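"""Top-enriched motif sets, position frequency matrices, and absence calls.

The most-enriched slice of the screen (top 5% = 400 motifs by default)
feeds a frequency-style sequence logo; the package emits the position
frequency matrix (PFM) and a residue color-group annotation for any
external logo renderer, plus a long-format (a1, a2, X, EF) table
sufficient to regenerate scatter views of the occupied sequence space.
Absence analysis reports residues never observed at a position within a
motif set, optionally conditioned on a residue at another position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import EFTable
from .motifs import AMINO_ACIDS, POSITIONS

#: Residue color groups for logo rendering (screen's custom scheme).
COLOR_SCHEME: dict[str, list[str]] = {
    "blue": ["C"],
    "green": ["D", "R", "E", "H", "K"],          # polar charged
    "black": ["N", "Q", "S", "T", "Y"],          # polar uncharged
    "red": ["I", "L", "V"],                      # branched chain
    "purple": ["A", "G", "M", "F", "P", "W"],    # all others
}


@dataclass
class PositionFrequencyMatrix:
    """Counts and frequencies of residues at a1/a2/X over a motif set."""

    counts: np.ndarray       # (3, 20) ints, rows = a1, a2, x
    n_motifs: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_motifs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, index=["a1", "a2", "x"],
                          columns=list(AMINO_ACIDS))
        return df


def top_fraction(table: EFTable, fraction: float = 0.05) -> list[str]:
    """The highest-EF motifs; count = round(fraction * table size).

    Ties at the boundary are broken lexicographically (the lexicographically
    earlier motif wins a contested slot), making the set deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = table.df
    k = int(round(fraction * len(df)))
    ef = df["ef"].to_numpy()
    motifs = df["motif"].to_numpy()
    # sort by EF descending, then motif ascending
    order = np.lexsort((motifs, -ef))
    return list(motifs[order[:k]])


def pfm(motifs: Sequence[str]) -> PositionFrequencyMatrix:
    """Position frequency matrix of a nonempty motif set."""
    if not motifs:
        raise ValueError("empty motif set")
    counts = np.zeros((3, 20), dtype=int)
    for m in motifs:
        for row, pos in enumerate(("a1", "a2", "x")):
            counts[row, AMINO_ACIDS.index(m[POSITIONS[pos]])] += 1
    return PositionFrequencyMatrix(counts=counts, n_motifs=len(motifs))


def absent_residues(
    motifs: Sequence[str],
    position: str,
    condition: Optional[tuple[str, str]] = None,
) -> set[str]:
    """Residues with zero occurrences at ``position`` within the set.

    ``condition`` = (other_position, residue) restricts the set first,
    mirroring axis-aligned views of the occupied space (e.g. absences at
    a2 among motifs with K at a1).  The result is exactly the alphabet
    minus the residues observed at the position.
    """
    if not motifs:
        raise ValueError("empty motif set")
    if position not in POSITIONS:
        raise ValueError(f"position must be one of {list(POSITIONS)}")
    subset = motifs
    if condition is not None:
        cpos, cres = condition
        if cpos == position:
            raise ValueError("conditioning position equals query position")
        subset = [m for m in motifs if m[POSITIONS[cpos]] == cres]
    seen = {m[POSITIONS[position]] for m in subset}
    return set(AMINO_ACIDS) - seen


def space_table(table: EFTable, motifs: Sequence[str]) -> pd.DataFrame:
    """Long-format (motif, a1, a2, x, ef) table for external scatter plots."""
    ef = table.df.set_index("motif")["ef"]
    return pd.DataFrame({
        "motif": list(motifs),
        "a1": [m[1] for m in motifs],
        "a2": [m[2] for m in motifs],
        "x": [m[3] for m in motifs],
        "ef": [float(ef[m]) for m in motifs],
    })


def write_pfm(matrix: PositionFrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_motifs={matrix.n_motifs}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="position")


def write_color_scheme(path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(COLOR_SCHEME, fh, indent=2)
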