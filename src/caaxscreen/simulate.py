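"""Synthetic competitive-growth screen over the full CXXX space.

The generator emulates the screen end to end so every pipeline stage is
testable without external sequencing data:

* a trimer-codon plasmid library of all 8,000 motifs with a lognormal
  abundance imbalance (roughly a 10x ratio between the extremes),
* rule-based prenylation ground truth mirroring the substrate rules the
  screen recovers (charged residues D/E/K/R restrictive at a2; K/P/R
  penalized at X unless rescued by I/L/M/V at a2; mild bonus for Q at X),
* ~8 generations of competitive growth where a motif's per-generation
  fitness advantage at the selective temperature is proportional to its
  prenylation propensity ((1 + s*p)^G, s = 0 at the permissive
  temperature),
* replicate structure (8 cultures per temperature by default) with
  multinomial read sampling, and optional FASTQ emission with the amplicon
  anchor context, Phred qualities, and an injectable fraction of junk
  reads to exercise the QC paths.

All randomness flows from the single seed in :class:`SimulationConfig`;
identical seeds give identical outputs byte for byte.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .extraction import ReplicateCounts
from .motifs import AMINO_ACIDS, N_MOTIFS, enumerate_cxxx, motif_to_insert

# Read layout: the read starts 38 bases upstream of the CXXX region, whose
# first codon is the fixed cysteine TGT (= the anchor's last 3 nt).
_UPSTREAM_38 = "ATTCCGATGAAGAAGAACAAGGTGGCGAAGGTGTACAA"
_CYS = "TGT"
_DOWNSTREAM = "TGATTTTCTTGATAAAAAAAGATCTTTCTAGAGCGGCCGCACTCGAGT"


@dataclass
class GroundTruthParams:
    """Rule parameters of the prenylation ground truth.

    Propensities: ``restricted`` when a2 carries a charged residue,
    ``low`` when X carries K/P/R without the aliphatic a2 rescue,
    ``high`` otherwise, plus ``q_bonus`` for Q at X (capped at 1).
    ``noise_sd`` adds truncated Gaussian noise; the default is 0 because
    additive noise clipped at 0 would bias the restricted class upward
    (a generator artifact), and read sampling already provides
    stochasticity.
    """

    restricted_a2: str = "DEKR"
    penalized_x: str = "KPR"
    rescue_a2: str = "ILMV"
    high: float = 0.95
    low: float = 0.45
    restricted: float = 0.0
    q_bonus: float = 0.05
    noise_sd: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of the simulated screen (defaults = the stated world)."""

    n_reads: int = 500_000            # reads per replicate
    n_replicates_25: int = 8
    n_replicates_37: int = 8
    generations: int = 8
    selection: float = 0.3            # per-generation advantage at 37C, p=1
    imbalance_sigma: float = 0.447    # lognormal sigma, ~10x p99.5/p0.5
    seed: int = 0
    junk_fraction: float = 0.02       # anchorless low-quality reads
    emit_fastq: bool = False
    gzip_fastq: bool = False
    read_length: int = 100
    quality_mean: float = 37.0        # per-base Phred, good reads
    quality_sd: float = 2.0
    quality_min: int = 30
    quality_max: int = 40
    junk_quality_mean: float = 12.0
    junk_quality_sd: float = 3.0
    truth: GroundTruthParams = field(default_factory=GroundTruthParams)

    def __post_init__(self) -> None:
        if self.selection < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.imbalance_sigma < 0:
            raise ValueError("imbalance_sigma must be >= 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def ground_truth_rules(
    motif: str,
    params: GroundTruthParams | None = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Prenylation propensity in [0, 1] of one motif under the rule set.

    Deterministic given motif, parameters and the rng state (the rng is
    consulted only when ``noise_sd > 0``).
    """
    params = params or GroundTruthParams()
    a2, x = motif[2], motif[3]
    if a2 in params.restricted_a2:
        p = params.restricted
    elif x in params.penalized_x and a2 not in params.rescue_a2:
        p = params.low
    else:
        p = params.high
        if x == "Q":
            p += params.q_bonus
    if params.noise_sd > 0 and rng is not None:
        p += float(rng.normal(0.0, params.noise_sd))
    return float(np.clip(p, 0.0, 1.0))


def ground_truth_all(
    params: GroundTruthParams | None = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Propensity vector over all 8,000 motifs (enumeration order)."""
    params = params or GroundTruthParams()
    motifs = enumerate_cxxx()
    a2 = np.array([AMINO_ACIDS.index(m[2]) for m in motifs])
    x = np.array([AMINO_ACIDS.index(m[3]) for m in motifs])
    in_set = lambda idx, s: np.isin(idx, [AMINO_ACIDS.index(r) for r in s])
    restricted = in_set(a2, params.restricted_a2)
    penalized = in_set(x, params.penalized_x) & ~in_set(a2, params.rescue_a2)
    p = np.full(N_MOTIFS, params.high)
    p[x == AMINO_ACIDS.index("Q")] += params.q_bonus
    p[penalized] = params.low
    p[restricted] = params.restricted
    if params.noise_sd > 0 and rng is not None:
        p = p + rng.normal(0.0, params.noise_sd, N_MOTIFS)
    return np.clip(p, 0.0, 1.0)


def simulate_library(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Naive library frequencies: normalized lognormal weights.

    ``imbalance_sigma = 0`` gives exactly uniform 1/8000.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.imbalance_sigma == 0:
        return np.full(N_MOTIFS, 1.0 / N_MOTIFS)
    w = rng.lognormal(mean=0.0, sigma=config.imbalance_sigma, size=N_MOTIFS)
    return w / w.sum()


def simulate_selection(
    naive: np.ndarray,
    propensity: np.ndarray,
    config: SimulationConfig,
    condition: str,
) -> np.ndarray:
    """Post-growth frequencies after G generations of competition.

    weight(m) = naive(m) * (1 + s*p(m))^G at the selective temperature;
    s is 0 at the permissive temperature, so 25C returns the input.
    """
    if condition not in ("25C", "37C"):
        raise ValueError("condition must be '25C' or '37C'")
    s = config.selection if condition == "37C" else 0.0
    w = np.asarray(naive, dtype=float) * (
        1.0 + s * np.asarray(propensity, dtype=float)) ** config.generations
    return w / w.sum()


def _phred_string(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + 33).tobytes().decode("ascii")


def _read_for_motif(motif: str, read_length: int) -> str:
    read = _UPSTREAM_38 + _CYS + motif_to_insert(motif) + _DOWNSTREAM
    return read[:read_length].ljust(read_length, "A")


def sample_reads(
    frequencies: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    replicate_id: str,
    condition: str,
    fastq_path: Optional[Path] = None,
) -> ReplicateCounts:
    """One replicate: a multinomial draw, optionally emitted as FASTQ.

    The returned :class:`ReplicateCounts` is the exact truth table of the
    draw (junk reads are extra and never enter the counts).  When a FASTQ
    is written, each real read embeds the anchor context, the motif's
    single-codon insert and the downstream stop context, with high-Phred
    qualities; junk reads are anchorless with low qualities.
    """
    motifs = enumerate_cxxx()
    draw = (rng.multinomial(config.n_reads, frequencies)
            if config.n_reads > 0 else np.zeros(N_MOTIFS, dtype=int))
    truth = Counter({motifs[i]: int(c) for i, c in enumerate(draw) if c > 0})
    n_junk = int(round(config.junk_fraction * config.n_reads))
    rep = ReplicateCounts(
        replicate_id=replicate_id, condition=condition,
        counts=truth, n_reads_total=config.n_reads,
        q30_fraction=(config.n_reads / (config.n_reads + n_junk)
                      if config.n_reads + n_junk > 0 else float("nan")),
    )

    if fastq_path is None:
        return rep

    L = config.read_length
    total = config.n_reads + n_junk
    # sequences, grouped by motif then shuffled together with the junk
    seqs: list[str] = []
    for i in np.nonzero(draw)[0]:
        seqs.extend([_read_for_motif(motifs[i], L)] * int(draw[i]))
    bases = np.array(list("ACGT"))
    for row in rng.integers(0, 4, size=(n_junk, L)):
        seqs.append("".join(bases[row]))
    is_junk = np.zeros(total, dtype=bool)
    is_junk[config.n_reads:] = True
    order = rng.permutation(total)

    good_q = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd,
                           size=(config.n_reads, L))),
        config.quality_min, config.quality_max).astype(np.uint8)
    junk_q = np.clip(
        np.rint(rng.normal(config.junk_quality_mean, config.junk_quality_sd,
                           size=(n_junk, L))),
        2, 25).astype(np.uint8)

    chunks: list[str] = []
    for k, idx in enumerate(order):
        if is_junk[idx]:
            qual = junk_q[idx - config.n_reads]
        else:
            qual = good_q[idx]
        chunks.append(
            f"@{replicate_id}.{k + 1}\n{seqs[idx]}\n+\n{_phred_string(qual)}\n")
    data = "".join(chunks)
    fastq_path = Path(fastq_path)
    if config.gzip_fastq or fastq_path.suffix == ".gz":
        import gzip
        with gzip.open(fastq_path, "wt", compresslevel=4) as fh:
            fh.write(data)
    else:
        fastq_path.write_text(data)
    # truth-table accounting covers the real reads; the junk reads exist
    # only in the emitted file and surface as rejections downstream
    return rep


@dataclass
class SimulatedScreen:
    """Everything one simulated screen produced."""

    config: SimulationConfig
    propensity: np.ndarray
    naive: np.ndarray
    freq25: np.ndarray
    freq37: np.ndarray
    replicates_25: list
    replicates_37: list
    fastq_paths: dict = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "motif": enumerate_cxxx(),
            "propensity": self.propensity,
            "naive_freq": self.naive,
        })


def run_screen(
    config: SimulationConfig,
    outdir: Optional[str | Path] = None,
) -> SimulatedScreen:
    """Simulate the whole screen: library, growth, replicate sampling.

    With ``emit_fastq`` and an ``outdir``, per-replicate FASTQ files,
    truth count tables, the ground-truth propensities and a manifest are
    written under ``outdir``.
    """
    rng = np.random.default_rng(config.seed)
    truth_rng = rng.spawn(1)[0]
    propensity = ground_truth_all(config.truth, truth_rng)
    naive = simulate_library(config, rng)
    freq25 = simulate_selection(naive, propensity, config, "25C")
    freq37 = simulate_selection(naive, propensity, config, "37C")

    outdir_p = Path(outdir) if outdir is not None else None
    if outdir_p is not None:
        outdir_p.mkdir(parents=True, exist_ok=True)

    screen = SimulatedScreen(
        config=config, propensity=propensity, naive=naive,
        freq25=freq25, freq37=freq37, replicates_25=[], replicates_37=[])

    for condition, freqs, n_reps, store in (
            ("25C", freq25, config.n_replicates_25, screen.replicates_25),
            ("37C", freq37, config.n_replicates_37, screen.replicates_37)):
        for r in range(n_reps):
            rep_id = f"{condition}_rep{r + 1}"
            fq = None
            if config.emit_fastq and outdir_p is not None:
                suffix = ".fastq.gz" if config.gzip_fastq else ".fastq"
                fq = outdir_p / f"{rep_id}{suffix}"
                screen.fastq_paths[rep_id] = fq
            rep = sample_reads(freqs, config, rng, rep_id, condition, fq)
            store.append(rep)

    if outdir_p is not None:
        from .extraction import write_counts
        for rep in screen.replicates_25 + screen.replicates_37:
            write_counts(rep, outdir_p / f"truth_{rep.replicate_id}.tsv")
        screen.truth_frame().to_csv(
            outdir_p / "ground_truth.tsv", sep="\t", index=False)
        cfg = asdict(config)
        manifest = {
            "config": cfg,
            "files": sorted(p.name for p in outdir_p.iterdir()),
        }
        with open(outdir_p / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return screen
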