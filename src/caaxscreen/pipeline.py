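"""End-to-end orchestration: count -> EF -> heatmaps/HM -> tree -> logo.

A run is driven by a single :class:`RunConfig` (loadable from YAML) and
writes every intermediate artifact to the output directory so any stage
can be audited or re-entered: count tables, the EF table, the three
heatmaps, the pattern report, the HM score table, the tree model and
rules, logo matrices, the benchmark report, and a manifest recording all
parameters and output checksums.

Entry points are flexible: start from per-replicate FASTQ files, from
pre-computed count tables, from an EF table, or from the built-in
simulator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .classify import benchmark_table3, format_benchmark, write_benchmark
from .enrichment import (EFTable, compute_ef, pool_replicates, read_ef_table,
                         write_ef_table)
from .extraction import (ExtractionConfig, count_replicate, qc_replicates,
                         read_counts, write_counts, write_qc_report)
from .heatmap import (PAIRS, build_all_heatmaps, detect_all_patterns,
                      hm_score_all, write_heatmap, write_pattern_report)
from .logo import (absent_residues, pfm, space_table, top_fraction,
                   write_color_scheme, write_pfm)
from .simulate import GroundTruthParams, SimulationConfig, run_screen
from .tree import binarize_labels, extract_rules, fit_tree_motifs, write_rules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; serialized into the run manifest."""

    outdir: str = "caaxscreen_run"
    seed: int = 0
    # inputs (choose one entry point; simulate wins if set)
    simulate: Optional[dict] = None          # SimulationConfig overrides
    fastq_25: Sequence[str] = field(default_factory=list)
    fastq_37: Sequence[str] = field(default_factory=list)
    counts_25: Sequence[str] = field(default_factory=list)
    counts_37: Sequence[str] = field(default_factory=list)
    ef_table: Optional[str] = None
    # stage parameters
    extraction: dict = field(default_factory=dict)   # ExtractionConfig kwargs
    ef_scale: str = "cpm"
    ef_pseudocount: float = 1.0
    heatmap_z: float = 1.96
    heatmap_min_members: int = 18
    tree_max_set_size: int = 5
    tree_max_depth: int = 3
    tree_min_samples: int = 50
    label_threshold: float = 1.0
    logo_fraction: float = 0.05
    run_benchmark: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written).

    Stage order: [simulate] -> count -> qc -> pool -> ef -> heatmaps ->
    patterns -> hmscore -> tree -> logo -> benchmark.  Any stage failure
    raises with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "caaxscreen_version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
    }

    def record(name: str, *paths: Path) -> None:
        manifest["stages"].append(name)
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    stage = "start"
    try:
        table: Optional[EFTable] = None
        if config.simulate is not None:
            stage = "simulate"
            _stage(stage)
            sim_kwargs = dict(config.simulate)
            truth_kwargs = sim_kwargs.pop("truth", {})
            sim_kwargs.setdefault("seed", config.seed)
            sim_cfg = SimulationConfig(
                truth=GroundTruthParams(**truth_kwargs), **sim_kwargs)
            simdir = outdir / "simulated"
            screen = run_screen(sim_cfg, outdir=simdir)
            record(stage)
            if sim_cfg.emit_fastq:
                config = RunConfig(**{
                    **config.to_dict(),
                    "simulate": None,
                    "fastq_25": [str(screen.fastq_paths[r.replicate_id])
                                 for r in screen.replicates_25],
                    "fastq_37": [str(screen.fastq_paths[r.replicate_id])
                                 for r in screen.replicates_37],
                })
                reps25, reps37 = None, None
            else:
                reps25 = screen.replicates_25
                reps37 = screen.replicates_37
        else:
            reps25 = reps37 = None

        if config.ef_table is not None:
            stage = "load_ef"
            _stage(stage)
            table = read_ef_table(config.ef_table)
        else:
            ext_cfg = ExtractionConfig(**config.extraction)
            if reps25 is None:
                stage = "count"
                _stage(stage)
                if config.fastq_25 and config.fastq_37:
                    reps25 = [count_replicate(p, ext_cfg, condition="25C")
                              for p in config.fastq_25]
                    reps37 = [count_replicate(p, ext_cfg, condition="37C")
                              for p in config.fastq_37]
                elif config.counts_25 and config.counts_37:
                    reps25 = [read_counts(p) for p in config.counts_25]
                    reps37 = [read_counts(p) for p in config.counts_37]
                    for rep in reps25:
                        rep.condition = "25C"
                    for rep in reps37:
                        rep.condition = "37C"
                else:
                    raise ValueError(
                        "no input: set simulate, fastq_25/37, counts_25/37 "
                        "or ef_table")
            countdir = outdir / "counts"
            countdir.mkdir(exist_ok=True)
            written = []
            for rep in [*reps25, *reps37]:
                p = countdir / f"{rep.replicate_id}.tsv"
                write_counts(rep, p)
                written.append(p)
            record("count", *written)

            stage = "qc"
            _stage(stage)
            reps25, qc25 = qc_replicates(reps25, ext_cfg)
            reps37, qc37 = qc_replicates(reps37, ext_cfg)
            qc_path = outdir / "qc_report.json"
            write_qc_report({"25C": qc25, "37C": qc37}, qc_path)
            record(stage, qc_path)

            stage = "ef"
            _stage(stage)
            table = compute_ef(pool_replicates(reps25),
                               pool_replicates(reps37),
                               scale=config.ef_scale,
                               pseudocount=config.ef_pseudocount)
            ef_path = outdir / "ef_table.tsv"
            write_ef_table(table, ef_path)
            record(stage, ef_path)

        stage = "heatmap"
        _stage(stage)
        table.require_full()
        heatmaps = build_all_heatmaps(table)
        hm_paths = []
        for pair in PAIRS:
            p = outdir / f"heatmap_{pair[0]}x{pair[1]}.tsv"
            write_heatmap(heatmaps[pair], p)
            hm_paths.append(p)
        record(stage, *hm_paths)

        stage = "patterns"
        _stage(stage)
        patterns = detect_all_patterns(
            heatmaps, z=config.heatmap_z,
            min_members=config.heatmap_min_members)
        pat_path = outdir / "patterns.json"
        write_pattern_report(patterns, pat_path, z=config.heatmap_z,
                             min_members=config.heatmap_min_members)
        record(stage, pat_path)

        stage = "hmscore"
        _stage(stage)
        scores = hm_score_all(table)
        hm_path = outdir / "hm_scores.tsv"
        scores.to_csv(hm_path, sep="\t", index=False,
                      float_format="%.6f")
        record(stage, hm_path)

        stage = "tree"
        _stage(stage)
        labeled = binarize_labels(table, config.label_threshold)
        model = fit_tree_motifs(
            labeled, max_set_size=config.tree_max_set_size,
            max_depth=config.tree_max_depth,
            min_samples=config.tree_min_samples)
        tree_path = outdir / "tree.json"
        model.to_json(tree_path)
        rules_path = outdir / "rules.txt"
        write_rules(extract_rules(model), rules_path)
        record(stage, tree_path, rules_path)

        stage = "logo"
        _stage(stage)
        top = top_fraction(table, config.logo_fraction)
        matrix = pfm(top)
        pfm_path = outdir / "top_pfm.tsv"
        write_pfm(matrix, pfm_path)
        colors_path = outdir / "logo_colors.json"
        write_color_scheme(colors_path)
        space_path = outdir / "top_space.tsv"
        space_table(table, top).to_csv(space_path, sep="\t", index=False,
                                       float_format="%.6f")
        absent = {pos: sorted(absent_residues(top, pos))
                  for pos in ("a1", "a2", "x")}
        absent_path = outdir / "top_absent_residues.json"
        with open(absent_path, "w") as fh:
            json.dump(absent, fh, indent=2)
        record(stage, pfm_path, colors_path, space_path, absent_path)

        if config.run_benchmark:
            stage = "benchmark"
            _stage(stage)
            report = benchmark_table3()
            bench_path = outdir / "benchmark.json"
            write_benchmark(report, bench_path)
            (outdir / "benchmark.txt").write_text(
                format_benchmark(report) + "\n")
            record(stage, bench_path, outdir / "benchmark.txt")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
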