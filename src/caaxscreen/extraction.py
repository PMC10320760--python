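"""Amplicon FASTQ to per-replicate CXXX count tables.

Reads carry a fixed anchor ending with the cysteine codon TGT directly
upstream of the nine variable nucleotides.  Extraction is anchor-search
based (position independent), falls back to the reverse complement, gates
each read on the mean Phred quality of the 9-nt insert, and keeps full
accounting: every read is either assigned to a motif or counted under a
rejection reason, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam
from Bio.Seq import reverse_complement

from .motifs import TranslationError, translate_insert

logger = logging.getLogger(__name__)

#: Rejection reasons, in reporting order.
REJECT_REASONS = ("no_anchor", "truncated", "low_quality", "invalid_base",
                  "stop_codon")


@dataclass
class ExtractionConfig:
    """Parameters of motif extraction and replicate-level QC.

    anchor
        Exact DNA anchor; its last three bases are the Cys codon, so the
        nine bases that follow it are the a1/a2/X codons.
    min_insert_quality
        Minimum mean Phred score over the 9-nt insert for a read to count.
    replicate_q30_fraction_min
        Replicates whose fraction of reads with mean Phred >= 30 falls
        below this are dropped by :func:`qc_replicates`.
    allow_one_mismatch
        Optional tolerant anchor match (off by default; the screen design
        gives no mismatch tolerance).
    """

    anchor: str = "GGTGGCGAAGGTGTACAATGT"
    min_insert_quality: float = 20.0
    replicate_q30_fraction_min: float = 0.8
    search_reverse_complement: bool = True
    allow_one_mismatch: bool = False


@dataclass
class ReplicateCounts:
    """Per-replicate motif counts plus read-level accounting."""

    replicate_id: str
    condition: str  # 25C, 37C, naive_ecoli, naive_yeast
    counts: Counter = field(default_factory=Counter)
    n_reads_total: int = 0
    n_rejected_by_reason: Counter = field(default_factory=Counter)
    q30_fraction: float = float("nan")

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        assigned = self.n_assigned
        rejected = sum(self.n_rejected_by_reason.values())
        if assigned + rejected != self.n_reads_total:
            raise ValueError(
                f"{self.replicate_id}: assigned ({assigned}) + rejected "
                f"({rejected}) != total reads ({self.n_reads_total})")


def _find_with_one_mismatch(seq: str, anchor: str) -> int:
    n, k = len(seq), len(anchor)
    for i in range(n - k + 1):
        mism = 0
        window = seq[i:i + k]
        for a, b in zip(window, anchor):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return i
    return -1


def extract_motif(
    seq: str,
    qualities: Optional[Sequence[int]],
    cfg: ExtractionConfig,
) -> tuple[Optional[str], Optional[str]]:
    """Extract the CXXX motif from one read.

    Returns ``(motif, None)`` on success or ``(None, reason)`` with reason
    in :data:`REJECT_REASONS`.  The anchor is searched on the forward
    strand first, then (if configured) on the reverse complement, taking
    the first occurrence.  ``qualities`` are per-base Phred scores aligned
    to ``seq``; ``None`` skips the quality gate.
    """
    seq = seq.upper()
    anchor = cfg.anchor

    def locate(s: str) -> int:
        if cfg.allow_one_mismatch:
            return _find_with_one_mismatch(s, anchor)
        return s.find(anchor)

    pos = locate(seq)
    quals = qualities
    if pos < 0 and cfg.search_reverse_complement:
        rc = reverse_complement(seq)
        pos = locate(rc)
        if pos >= 0:
            seq = rc
            quals = qualities[::-1] if qualities is not None else None
    if pos < 0:
        return None, "no_anchor"

    start = pos + len(anchor)
    insert = seq[start:start + 9]
    if len(insert) < 9:
        return None, "truncated"
    if quals is not None:
        iq = quals[start:start + 9]
        if len(iq) == 9 and sum(iq) / 9.0 < cfg.min_insert_quality:
            return None, "low_quality"
    try:
        a1, a2, x = translate_insert(insert)
    except TranslationError as err:
        return None, err.reason
    return "C" + a1 + a2 + x, None


def count_replicate(
    fastq_path: str | Path,
    cfg: ExtractionConfig,
    replicate_id: Optional[str] = None,
    condition: str = "",
) -> ReplicateCounts:
    """Count CXXX motifs in one FASTQ file (plain or gzip).

    Also records the replicate's Q30 fraction (reads whose mean Phred over
    the whole read is >= 30) for downstream replicate-level QC.
    """
    fastq_path = Path(fastq_path)
    rep = ReplicateCounts(
        replicate_id=replicate_id or fastq_path.stem,
        condition=condition,
    )
    n_q30 = 0
    record_no = 0
    try:
        with pysam.FastxFile(str(fastq_path)) as fh:
            for entry in fh:
                record_no += 1
                rep.n_reads_total += 1
                quals = entry.get_quality_array()
                if quals is not None and len(quals) > 0:
                    if sum(quals) / len(quals) >= 30.0:
                        n_q30 += 1
                motif, reason = extract_motif(entry.sequence, quals, cfg)
                if motif is not None:
                    rep.counts[motif] += 1
                else:
                    rep.n_rejected_by_reason[reason] += 1
    except (OSError, ValueError) as err:
        raise RuntimeError(
            f"unreadable or truncated FASTQ {fastq_path} "
            f"at record {record_no + 1}: {err}") from err
    if rep.n_reads_total == 0:
        logger.warning("empty FASTQ: %s", fastq_path)
        rep.q30_fraction = float("nan")
    else:
        rep.q30_fraction = n_q30 / rep.n_reads_total
    rep.validate()
    return rep


def qc_replicates(
    replicates: Sequence[ReplicateCounts],
    cfg: ExtractionConfig,
) -> tuple[list[ReplicateCounts], dict]:
    """Drop replicates below the Q30-fraction threshold.

    Returns the retained replicates and a QC report (per-replicate Q30
    fractions, the threshold, and the retain/drop decision).  Raises if
    nothing survives.
    """
    if not replicates:
        raise ValueError("no replicates given")
    threshold = cfg.replicate_q30_fraction_min
    report = {"threshold_q30_fraction": threshold, "replicates": []}
    retained = []
    for rep in replicates:
        ok = rep.q30_fraction >= threshold or threshold <= 0
        report["replicates"].append({
            "replicate_id": rep.replicate_id,
            "condition": rep.condition,
            "n_reads_total": rep.n_reads_total,
            "q30_fraction": rep.q30_fraction,
            "retained": bool(ok),
        })
        if ok:
            retained.append(rep)
    if not retained:
        raise ValueError(
            f"all {len(replicates)} replicates fail the Q30 fraction "
            f"threshold {threshold}")
    return retained, report


def write_counts(rep: ReplicateCounts, path: str | Path) -> None:
    """Write a per-replicate count table as TSV (motif, count)."""
    path = Path(path)
    df = pd.DataFrame(
        sorted(rep.counts.items()), columns=["motif", "count"])
    with open(path, "w") as fh:
        fh.write(f"# replicate_id={rep.replicate_id}\n")
        fh.write(f"# condition={rep.condition}\n")
        fh.write(f"# n_reads_total={rep.n_reads_total}\n")
        fh.write(f"# q30_fraction={rep.q30_fraction}\n")
        for reason in REJECT_REASONS:
            fh.write(f"# rejected_{reason}={rep.n_rejected_by_reason[reason]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path: str | Path) -> ReplicateCounts:
    """Read a count table written by :func:`write_counts`."""
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
    rep = ReplicateCounts(
        replicate_id=meta.get("replicate_id", Path(path).stem),
        condition=meta.get("condition", ""),
        counts=Counter(dict(zip(df["motif"], df["count"].astype(int))))
        if len(df) else Counter(),
        n_reads_total=int(meta.get("n_reads_total", 0)),
        q30_fraction=float(meta.get("q30_fraction", "nan")),
    )
    for reason in REJECT_REASONS:
        key = f"rejected_{reason}"
        if key in meta:
            n = int(meta[key])
            if n:
                rep.n_rejected_by_reason[reason] = n
    return rep


def write_qc_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
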