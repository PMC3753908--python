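"""End-to-end orchestration: inputs -> DE -> clustering -> enrichment -> methylation.

A single root seed deterministically spawns per-stage substreams (stable
labels), so rerunning a stage or adding one never perturbs the draws of
the others and a fixed config yields a byte-identical run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_test, detect_clusters
from .core import (
    GeneAnnotationSet,
    RepeatAnnotationSet,
    read_gene_annotation,
    read_repeat_annotation,
    write_gene_annotation,
    write_repeat_annotation,
    logger,
)
from .diffexpr import (
    ExpressionMatrix,
    aggregate_genes,
    classify_probes,
    gene_calls_frame,
    moderated_t,
    probe_stats_frame,
)
from .enrichment import enrichment_screen
from .methylation import MethylationTable, compare_all
from .probemap import ProbeGeneMap, filter_unique, read_probe_map
from .simulate import (
    DEFAULT_METHYLATION_PANEL,
    SimulationConfig,
    generate_expression,
    generate_genome,
    generate_methylation,
    generate_repeats,
    substream_seed,
    write_expression,
    write_truth,
)


@dataclass
class PipelineConfig:
    """Run configuration; either synthetic mode or explicit input paths."""

    seed: int = 0
    outdir: str = "derepress_out"
    synthetic: bool = True
    simulation: SimulationConfig | None = None
    # input paths (used when synthetic is False)
    annotation_path: str | None = None
    annotation_format: str = "BED"
    chrom_sizes_path: str | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    probe_map_path: str | None = None
    repeats_path: str | None = None
    repeats_format: str = "rmsk"
    methylation_path: str | None = None
    # thresholds
    fdr_stringent: float = 0.10
    fdr_relaxed: float = 0.30
    max_gap_bp: int = 500_000
    alpha: float = 0.05
    cluster_alpha: float = 0.001
    n_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("cluster_gene_range", "cluster_span_range", "fold_range",
                        "probes_per_gene_range", "gene_length_range",
                        "enriched_families", "background_families"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def echo(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
        return out


@dataclass
class Finding:
    level: str  # "warning" | "fatal"
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Structural and range checks; fatal findings abort the run."""
    findings: list[Finding] = []
    if config.n_iter < 1:
        findings.append(Finding("fatal", "n_iter must be >= 1"))
    for name in ("fdr_stringent", "fdr_relaxed", "alpha", "cluster_alpha"):
        v = getattr(config, name)
        if not 0.0 < v <= 1.0:
            findings.append(Finding("fatal", f"{name} must lie in (0, 1]"))
    if config.fdr_relaxed < config.fdr_stringent:
        findings.append(Finding("fatal", "fdr_relaxed must be >= fdr_stringent"))
    if config.max_gap_bp <= 0:
        findings.append(Finding("fatal", "max_gap_bp must be positive"))
    if not config.synthetic:
        for name in ("annotation_path", "expression_path", "samples_path",
                     "probe_map_path", "repeats_path"):
            if getattr(config, name) is None:
                findings.append(Finding("fatal", f"{name} required when not synthetic"))
        if config.chrom_sizes_path is None:
            findings.append(
                Finding("fatal", "chrom_sizes_path required: resampling needs true lengths")
            )
    return findings


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run report.

    Intermediate files are written under ``config.outdir`` as each stage
    completes, so a failing stage leaves partial outputs behind.
    """
    findings = validate_config(config)
    fatal = [f.message for f in findings if f.level == "fatal"]
    if fatal:
        raise ValueError("invalid config: " + "; ".join(fatal))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": {},
    }

    stage = "inputs"
    try:
        if config.synthetic:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            if config.simulation is None:
                sim = dataclasses.replace(sim, seed=config.seed)
            annotation, truth = generate_genome(sim)
            matrix_df, samples, relations = generate_expression(annotation, truth, sim)
            repeats = generate_repeats(annotation, truth, sim)
            groups = [(s, samples.loc[s, "group"]) for s in samples.index]
            meth = MethylationTable(
                generate_methylation(
                    DEFAULT_METHYLATION_PANEL, groups,
                    substream_seed(sim.seed, "methylation"),
                )
            )
            write_gene_annotation(annotation, outdir / "genes.bed")
            write_repeat_annotation(repeats, outdir / "repeats.bed")
            write_expression(matrix_df, samples, relations, outdir)
            write_truth(truth, sim, outdir / "truth.yaml")
            meth.write(outdir / "methylation.tsv")
            pmap = ProbeGeneMap(
                relations={p: set(g) for p, g in relations.items()},
                gene_universe=len(annotation),
            )
            matrix = ExpressionMatrix(values=matrix_df, samples=samples)
        else:
            annotation = read_gene_annotation(
                config.annotation_path, config.annotation_format, config.chrom_sizes_path
            )
            repeats = read_repeat_annotation(config.repeats_path, config.repeats_format)
            matrix = ExpressionMatrix.read(config.expression_path, config.samples_path)
            pmap = read_probe_map(config.probe_map_path, gene_universe=len(annotation))
            meth = (
                MethylationTable.read(config.methylation_path)
                if config.methylation_path
                else None
            )
        report["stages"]["inputs"] = {
            "n_genes": len(annotation),
            "n_probes": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
            "n_repeat_elements": len(repeats),
        }

        stage = "probe_mapping"
        unique_map, mapping = filter_unique(pmap)
        (outdir / "mapping_summary.json").write_text(mapping.to_json())
        report["stages"]["probe_mapping"] = json.loads(mapping.to_json())

        stage = "differential_expression"
        probe_stats = moderated_t(matrix, shrinkage="on")
        classify_probes(probe_stats, config.fdr_stringent, config.fdr_relaxed)
        calls = aggregate_genes(probe_stats, unique_map)
        probe_stats_frame(probe_stats).to_csv(outdir / "probe_stats.tsv", sep="\t")
        gene_calls_frame(calls).to_csv(outdir / "gene_calls.tsv", sep="\t")
        de_counts = {
            "probes_stringent": sum(s.category == "stringent" for s in probe_stats),
            "probes_relaxed": sum(s.category == "relaxed" for s in probe_stats),
            "probes_up": sum(s.direction == "up" for s in probe_stats),
            "probes_down": sum(s.direction == "down" for s in probe_stats),
            "genes_upregulated": sum(c.status == "upregulated" for c in calls),
            "genes_downregulated": sum(c.status == "downregulated" for c in calls),
            "genes_conflicted": sum(c.status == "conflicted" for c in calls),
            "genes_no_change": sum(c.status == "no_change" for c in calls),
        }
        report["stages"]["differential_expression"] = de_counts

        stage = "cluster_analysis"
        up_genes = [c.gene_id for c in calls if c.status == "upregulated"]
        # null universe: array-represented genes (those covered by the unique map)
        covered = {next(iter(g)) for g in unique_map.relations.values()}
        universe = annotation.subset(covered)
        cluster_stage: dict[str, Any] = {"n_called_up": len(up_genes)}
        clusters = []
        if len(up_genes) >= 2:
            chrom = annotation.interval_of(up_genes[0]).chrom
            result = cluster_test(
                up_genes, universe, chrom, config.n_iter,
                np.random.SeedSequence(substream_seed(config.seed, "cluster_test")),
            )
            clusters, frac = detect_clusters(up_genes, annotation, config.max_gap_bp)
            pd.DataFrame({"null_median_bp": result.null_medians}).to_csv(
                outdir / "cluster_null.tsv", sep="\t", index=False
            )
            with open(outdir / "clusters.bed", "w") as fh:
                for i, cl in enumerate(clusters, 1):
                    fh.write(
                        f"{cl.span.chrom}\t{cl.span.start}\t{cl.span.end}\tcluster_{i}"
                        f"\t{cl.n_genes}\t.\n"
                    )
            cluster_stage.update(
                observed_median_bp=result.observed_median_bp,
                null_mean_bp=result.null_mean_bp,
                null_ci95=list(result.null_ci95),
                p_parametric=result.p_parametric,
                p_empirical=result.p_empirical,
                significant=bool(result.p_empirical <= config.cluster_alpha),
                n_clusters=len(clusters),
                cluster_sizes=[c.n_genes for c in clusters],
                cluster_spans_bp=[c.span.length for c in clusters],
                fraction_clustered=frac,
            )
        else:
            cluster_stage["note"] = "fewer than 2 upregulated genes; test skipped"
        report["stages"]["cluster_analysis"] = cluster_stage

        stage = "feature_enrichment"
        enr_stage: dict[str, Any] = {}
        if clusters:
            chrom = clusters[0].span.chrom
            chrom_length = annotation.chrom_lengths[chrom]
            results = enrichment_screen(
                clusters, repeats, chrom_length, config.n_iter,
                substream_seed(config.seed, "enrichment"), config.alpha,
            )
            rows = [
                {
                    "family": r.family,
                    "cluster_counts": ",".join(map(str, r.cluster_counts)),
                    "null_mean": r.null_mean,
                    "p_wilcoxon": r.p_wilcoxon,
                    "method": r.method,
                    "enriched": r.enriched,
                }
                for r in results
            ]
            pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            enr_stage = {
                "n_candidate_families": len(results),
                "families": {r.family: r.p_wilcoxon for r in results},
                "enriched_families": sorted(r.family for r in results if r.enriched),
            }
        else:
            enr_stage["note"] = "no clusters; enrichment skipped"
        report["stages"]["feature_enrichment"] = enr_stage

        stage = "methylation"
        if meth is not None:
            comparisons = compare_all(meth, alpha=config.alpha)
            comparisons.to_csv(outdir / "methylation_comparisons.tsv", sep="\t")
            report["stages"]["methylation"] = {
                "n_amplicons": int(len(comparisons)),
                "significant": sorted(
                    comparisons.index[comparisons["significant"].astype(bool)]
                ),
                "p_values": {a: float(p) for a, p in comparisons["p"].items()},
            }
        else:
            report["stages"]["methylation"] = {"note": "no methylation input"}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished; report at %s", outdir / "report.json")
    return report
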