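"""Pooling, frequencies, and the enrichment factor (EF).

Replicate counts are summed within a temperature condition, converted to
frequencies, and the EF of each motif is the ratio of its abundance at the
selective temperature (37C) to the permissive temperature (25C), with a +1
pseudocount so motifs that drop out at 25C stay finite:

    EF(m) = (v37(m) + pseudocount) / (v25(m) + pseudocount)

where v is the motif abundance on a configurable scale.  The default scale
is counts per million of the pooled condition: a +1 offset on literal
fractional frequencies would compress every EF to ~1, so the pseudocount
is applied on a count-like scale and the choice is recorded in the table
metadata and all downstream outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import ReplicateCounts
from .motifs import AMINO_ACIDS, N_MOTIFS, enumerate_cxxx

SCALES = ("cpm", "raw_count", "fraction")


@dataclass
class ConditionCounts:
    """Pooled counts for one condition over the full motif space."""

    condition: str
    counts: Counter
    total: int

    @classmethod
    def from_replicates(cls, replicates: Sequence[ReplicateCounts]
                        ) -> "ConditionCounts":
        return pool_replicates(replicates)


@dataclass
class EFTable:
    """Per-motif frequencies and enrichment factors for one screen.

    ``df`` has columns motif, freq25, freq37, ef; ``metadata`` records the
    pseudocount mode so every downstream artifact can state how EFs were
    derived.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ef(self) -> pd.Series:
        return self.df.set_index("motif")["ef"]

    def require_full(self) -> None:
        """Raise unless the table covers all 8,000 motifs exactly once."""
        if len(self.df) != N_MOTIFS or self.df["motif"].duplicated().any():
            missing = set(enumerate_cxxx()) - set(self.df["motif"])
            first = sorted(missing)[0] if missing else "(duplicates present)"
            raise ValueError(
                f"EF table does not cover the 8,000-motif space; "
                f"first absent motif: {first}")


def pool_replicates(replicates: Sequence[ReplicateCounts]) -> ConditionCounts:
    """Sum motif counts across replicates of one condition."""
    if not replicates:
        raise ValueError("no replicates to pool")
    conditions = {rep.condition for rep in replicates}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in pool: {sorted(conditions)}")
    pooled: Counter = Counter()
    for rep in replicates:
        pooled.update(rep.counts)
    return ConditionCounts(
        condition=conditions.pop(),
        counts=pooled,
        total=sum(pooled.values()),
    )


def compute_ef(
    c25: ConditionCounts,
    c37: ConditionCounts,
    scale: str = "cpm",
    pseudocount: float = 1.0,
) -> EFTable:
    """Build the EF table over all 8,000 motifs.

    Frequencies (freq25/freq37 columns) are plain fractions of the pooled
    condition totals regardless of ``scale``; the pseudocount is applied on
    the chosen scale only for the EF ratio.  Motifs absent from both
    conditions get EF = 1 so contextual averages always see 20 members.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")
    if c25.total == 0 or c37.total == 0:
        raise ValueError("zero total counts in a condition")
    motifs = enumerate_cxxx()
    n25 = np.array([c25.counts.get(m, 0) for m in motifs], dtype=float)
    n37 = np.array([c37.counts.get(m, 0) for m in motifs], dtype=float)
    freq25 = n25 / c25.total
    freq37 = n37 / c37.total
    if scale == "cpm":
        v25, v37 = freq25 * 1e6, freq37 * 1e6
    elif scale == "raw_count":
        v25, v37 = n25, n37
    else:  # literal fractional frequencies, as the source text reads
        v25, v37 = freq25, freq37
    ef = (v37 + pseudocount) / (v25 + pseudocount)
    df = pd.DataFrame(
        {"motif": motifs, "freq25": freq25, "freq37": freq37, "ef": ef})
    return EFTable(df, metadata={
        "scale": scale,
        "pseudocount": pseudocount,
        "total_25": c25.total,
        "total_37": c37.total,
    })


def assign_quartiles(table: EFTable) -> pd.Series:
    """Quartile (1..4) of each motif by EF rank; 4 = most enriched.

    Ties are broken by motif lexicographic order, so quartiles are exact
    deterministic 2,000-member blocks on a full table.
    """
    df = table.df
    order = np.lexsort((df["motif"].to_numpy(), df["ef"].to_numpy()))
    n = len(df)
    quart = np.empty(n, dtype=int)
    # rank 0 = lowest EF -> quartile 1
    quart[order] = 1 + (np.arange(n) * 4) // n
    return pd.Series(quart, index=df["motif"], name="quartile")


def subgroup_mean_ef(
    table: EFTable,
    a1_set: Optional[str | set] = None,
    a2_set: Optional[str | set] = None,
    x_set: Optional[str | set] = None,
) -> tuple[int, float, float]:
    """(n, mean EF, population SD) over motifs restricted by residue sets.

    ``None`` leaves a position unrestricted.  Returns ``(0, nan, nan)``
    for an empty intersection.
    """
    def as_set(s):
        if s is None:
            return set(AMINO_ACIDS)
        s = set(s)
        if not s:
            raise ValueError("empty residue set (use None for unrestricted)")
        bad = s - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues: {sorted(bad)}")
        return s

    s1, s2, sx = as_set(a1_set), as_set(a2_set), as_set(x_set)
    motifs = table.df["motif"]
    mask = (motifs.str[1].isin(s1) & motifs.str[2].isin(s2)
            & motifs.str[3].isin(sx)).to_numpy()
    n = int(mask.sum())
    if n == 0:
        return 0, float("nan"), float("nan")
    vals = table.df.loc[mask, "ef"].to_numpy()
    return n, float(vals.mean()), float(vals.std(ddof=0))


def write_ef_table(table: EFTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in table.metadata.items():
            fh.write(f"# {key}={val}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_ef_table(path: str | Path) -> EFTable:
    """Read an EF table (ours or externally produced, e.g. a published
    screen's table with the same columns)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if "motif" not in df.columns or "ef" not in df.columns:
        raise ValueError(f"{path}: EF table needs 'motif' and 'ef' columns")
    return EFTable(df, metadata=meta)
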