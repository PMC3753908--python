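"""Synthetic data with known ground truth.

Generates gene annotation with planted positional clusters of upregulated
genes, a matching log2 expression matrix and probe map, repeat annotation
with planted family enrichment inside the clusters, and Sequenom-style
methylation tables plus bisulfite clone sequences. Every generator is a
pure function of its config (including the seed).

The defaults encode the biological scenario the package targets: a mouse
X chromosome (~166.65 Mb) carrying 569 array-represented genes of which
~10% shift from monoallelic to biallelic expression (1.2-2x, i.e. at most
a doubling), ~70% of the affected genes lying in 9 clusters of 2-12 genes
spanning 65 kb-1.5 Mb, with two SINE subtypes enriched inside the
clusters, and uniparental-type (~30-50%) methylation panels that lose
methylation in the mutant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import (
    GeneAnnotationSet,
    GenomicInterval,
    RepeatAnnotationSet,
    logger,
)

#: mouse X chromosome length, NCBI m37 assembly
MOUSE_X_LENGTH = 166_650_296

DEFAULT_ENRICHED_FAMILIES = ("B2_Mm1a", "ID4")
DEFAULT_BACKGROUND_FAMILIES = (
    "B1_Mus1",
    "B1_Mus2",
    "B2_Mm2",
    "L1Md_A",
    "L1Md_F2",
    "MIR",
    "ID_B1",
    "RSINE1",
)


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world; defaults are the target scenario."""

    seed: int = 0
    n_genes_x: int = 569
    chrom: str = "chrX"
    chrom_length_bp: int = MOUSE_X_LENGTH
    n_clusters: int = 9
    cluster_gene_range: tuple[int, int] = (2, 12)
    cluster_span_range: tuple[int, int] = (65_000, 1_500_000)
    affected_fraction: float = 0.10
    clustered_fraction: float = 0.70
    fold_range: tuple[float, float] = (1.2, 2.0)
    n_samples_per_group: int = 3
    noise_sd: float = 0.25
    probes_per_gene_range: tuple[int, int] = (1, 3)
    multi_map_fraction: float = 0.0
    enriched_families: tuple[str, ...] = DEFAULT_ENRICHED_FAMILIES
    background_families: tuple[str, ...] = DEFAULT_BACKGROUND_FAMILIES
    enrichment_factor: float = 10.0
    background_repeat_density: float = 5.0  # elements per Mb per family
    gene_length_range: tuple[int, int] = (1_000, 20_000)
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    probe_offset_sd: float = 0.5
    cluster_separation_bp: int = 3_000_000
    scattered_margin_bp: int = 1_000_000

    def validate(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigurationError("affected_fraction must be in [0,1]")
        if not 0.0 <= self.clustered_fraction <= 1.0:
            raise ConfigurationError("clustered_fraction must be in [0,1]")
        if self.fold_range[0] < 1.0 or self.fold_range[1] < self.fold_range[0]:
            raise ConfigurationError("fold_range must satisfy 1 <= low <= high")
        if min(self.n_genes_x, self.n_clusters, self.n_samples_per_group) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.cluster_gene_range[0] < 2:
            raise ConfigurationError("clusters need >= 2 genes")
        if not 0.0 <= self.multi_map_fraction <= 1.0:
            raise ConfigurationError("multi_map_fraction must be in [0,1]")
        if self.enrichment_factor < 1.0:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if self.chrom_length_bp <= 0:
            raise ConfigurationError("chrom_length_bp must be positive")


@dataclass
class TruthTable:
    """Ground truth of one synthetic genome: what was planted where."""

    affected_fold: dict[str, float] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    cluster_spans: list[GenomicInterval] = field(default_factory=list)
    enriched_families: tuple[str, ...] = ()

    @property
    def affected_genes(self) -> set[str]:
        return set(self.affected_fold)

    @property
    def clustered_genes(self) -> set[str]:
        return {g for cluster in self.clusters for g in cluster}


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------


def _partition_cluster_sizes(
    total: int, n_clusters: int, lo: int, hi: int, rng: np.random.Generator
) -> list[int]:
    """Split `total` genes into n_clusters sizes, each within [lo, hi]."""
    if total < n_clusters * lo or total > n_clusters * hi:
        raise ConfigurationError(
            f"cannot place {total} clustered genes into {n_clusters} clusters "
            f"of {lo}-{hi} genes"
        )
    sizes = [lo] * n_clusters
    remaining = total - n_clusters * lo
    while remaining > 0:
        open_idx = [i for i, s in enumerate(sizes) if s < hi]
        sizes[int(rng.choice(open_idx))] += 1
        remaining -= 1
    return sizes


def _place_cluster_spans(
    sizes: Sequence[int], config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Pick non-overlapping (start, span_length) pairs, one per cluster.

    Span length is coupled to cluster size (<= (k-1) * 300 kb) so that
    successive within-cluster gaps stay locally dense; spans are kept
    `cluster_separation_bp` apart so planted clusters are distinct
    spatial entities.
    """
    lo_span, hi_span = config.cluster_span_range
    placed: list[tuple[int, int]] = []
    for k in sizes:
        hi_k = min(hi_span, (k - 1) * 300_000)
        lo_k = min(lo_span, hi_k)
        span = int(rng.integers(lo_k, hi_k + 1))
        for _ in range(10_000):
            start = int(rng.integers(0, config.chrom_length_bp - span))
            sep = config.cluster_separation_bp
            if all(
                start < s - sep - span or start > s + sp + sep
                for s, sp in placed
            ):
                placed.append((start, span))
                break
        else:
            raise ConfigurationError(
                "could not place non-overlapping cluster spans; chromosome too "
                "short for the requested cluster layout"
            )
    return placed


def _cluster_member_starts(
    span_start: int, span_len: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Member gene starts: evenly spaced across the span with +/-30% jitter.

    First and last members pin the span ends so the realized span matches
    the drawn one; jitter keeps successive gaps within ~1.6x the mean gap.
    """
    if k == 2:
        return np.array([span_start, span_start + span_len], dtype=np.int64)
    spacing = span_len / (k - 1)
    offsets = np.arange(k) * spacing
    jitter = rng.uniform(-0.3, 0.3, size=k) * spacing
    jitter[0] = jitter[-1] = 0.0
    return span_start + np.round(offsets + jitter).astype(np.int64)


def generate_genome(config: SimulationConfig) -> tuple[GeneAnnotationSet, TruthTable]:
    """Place genes on one chromosome with planted clusters of affected genes.

    Affected genes fill the planted clusters first (sizes drawn from
    ``cluster_gene_range``); the remaining affected genes are scattered
    away from the cluster neighbourhoods; unaffected genes are uniform.
    Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes_x
    truth = TruthTable(enriched_families=tuple(config.enriched_families))
    if n == 0:
        return GeneAnnotationSet(genes=[], chrom_lengths={config.chrom: config.chrom_length_bp}), truth

    n_affected = int(round(config.affected_fraction * n))
    lo_k, hi_k = config.cluster_gene_range
    n_clusters = config.n_clusters
    n_clustered = int(round(config.clustered_fraction * n_affected))
    if n_clusters == 0 or n_clustered < 2:
        n_clusters, n_clustered = 0, 0
    else:
        n_clustered = min(n_clustered, n_affected, n_clusters * hi_k)
        if n_clustered < n_clusters * lo_k:
            raise ConfigurationError(
                f"{n_clustered} clustered genes cannot fill {n_clusters} "
                f"clusters of >= {lo_k} genes"
            )

    glen_lo, glen_hi = config.gene_length_range
    if glen_hi >= config.chrom_length_bp:
        raise ConfigurationError("gene length exceeds chromosome length")

    starts: list[int] = []
    cluster_assignment: list[list[int]] = []  # indices into the gene list
    if n_clusters:
        sizes = _partition_cluster_sizes(n_clustered, n_clusters, lo_k, hi_k, rng)
        spans = _place_cluster_spans(sizes, config, rng)
        for k, (span_start, span_len) in zip(sizes, spans):
            member_starts = _cluster_member_starts(span_start, span_len, k, rng)
            idx0 = len(starts)
            starts.extend(int(s) for s in member_starts)
            cluster_assignment.append(list(range(idx0, idx0 + k)))

    # scattered affected genes: away from planted cluster neighbourhoods
    span_windows = [
        (s - config.scattered_margin_bp, s + sp + config.scattered_margin_bp)
        for s, sp in (spans if n_clusters else [])
    ]
    # A scattered gene within max-gap of another affected gene would form an
    # injected-but-unrecorded cluster, breaking the truth table's completeness;
    # keep scattered genes out of the margin around spans and one another.
    n_scattered = n_affected - n_clustered
    scattered_idx: list[int] = []
    scattered_pos: list[int] = []
    hi_start = config.chrom_length_bp - glen_hi
    margin = config.scattered_margin_bp
    for _ in range(n_scattered):
        for _ in range(10_000):
            s = int(rng.integers(0, hi_start))
            if all(not (lo <= s <= hi) for lo, hi in span_windows) and all(
                abs(s - other) > margin for other in scattered_pos
            ):
                break
        scattered_idx.append(len(starts))
        scattered_pos.append(s)
        starts.append(s)

    # unaffected background genes: uniform anywhere
    n_background = n - n_affected
    bg = rng.integers(0, hi_start, size=n_background)
    starts.extend(int(s) for s in bg)

    lengths = rng.integers(glen_lo, glen_hi + 1, size=len(starts))
    order = np.argsort(np.array(starts, dtype=np.int64), kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    width = max(4, len(str(len(starts))))
    names = [f"gene{rank[i] + 1:0{width}d}" for i in range(len(starts))]

    genes = []
    for pos in order:
        start = starts[pos]
        end = min(start + int(lengths[pos]), config.chrom_length_bp)
        genes.append((names[pos], GenomicInterval(config.chrom, start, end, "+")))
    annotation = GeneAnnotationSet(
        genes=genes, chrom_lengths={config.chrom: config.chrom_length_bp}
    )

    folds = rng.uniform(config.fold_range[0], config.fold_range[1], size=n_affected)
    affected_idx = [i for cl in cluster_assignment for i in cl] + scattered_idx
    truth.affected_fold = {
        names[i]: float(f) for i, f in zip(affected_idx, folds)
    }
    truth.clusters = [[names[i] for i in cl] for cl in cluster_assignment]
    for cl in cluster_assignment:
        ivs = [genes[rank[i]][1] for i in cl]
        truth.cluster_spans.append(
            GenomicInterval(
                config.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
            )
        )
    _audit_truth(annotation, truth, config)
    return annotation, truth


def _audit_truth(
    annotation: GeneAnnotationSet, truth: TruthTable, config: SimulationConfig
) -> None:
    """Self-audit: the recorded truth must match what was injected."""
    gene_ids = set(annotation.gene_ids())
    if not truth.affected_genes <= gene_ids:
        raise AssertionError("truth lists affected genes missing from annotation")
    lo, hi = config.fold_range
    if any(not lo <= f <= hi for f in truth.affected_fold.values()):
        raise AssertionError("planted fold outside fold_range")
    if not truth.clustered_genes <= truth.affected_genes:
        raise AssertionError("clustered genes must be affected")
    for members, span in zip(truth.clusters, truth.cluster_spans):
        for g in members:
            iv = annotation.interval_of(g)
            if iv.start < span.start or iv.start > span.end:
                raise AssertionError("cluster member outside recorded span")


# ---------------------------------------------------------------------------
# Expression matrix + probe map
# ---------------------------------------------------------------------------


def generate_expression(
    annotation: GeneAnnotationSet,
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]]]:
    """Simulate a log2 expression matrix plus probe->gene relations.

    Returns (values, sample_sheet, relations): values is probe x sample;
    the sample sheet has columns group/sex. Mutant samples of affected
    genes are shifted by log2(planted fold); noise is i.i.d. Gaussian.
    A ``multi_map_fraction`` of probe sets is additionally assigned to a
    second gene (and is therefore dropped by the uniqueness filter).
    """
    config.validate()
    rng = np.random.default_rng(_substream(config.seed, "expression"))
    gene_ids = annotation.gene_ids()
    n_genes = len(gene_ids)
    if n_genes == 0:
        samples = _sample_sheet(config)
        return pd.DataFrame(columns=samples.index), samples, {}

    # baseline log2 abundance: Normal(6, 2) truncated at 0
    a = (0.0 - config.baseline_mean) / config.baseline_sd
    baseline = stats.truncnorm.rvs(
        a, np.inf, loc=config.baseline_mean, scale=config.baseline_sd,
        size=n_genes, random_state=rng,
    )
    p_lo, p_hi = config.probes_per_gene_range
    probes_per_gene = rng.integers(p_lo, p_hi + 1, size=n_genes)
    gene_of_probe = np.repeat(np.arange(n_genes), probes_per_gene)
    n_probes = gene_of_probe.size
    probe_ids = [
        f"ps{gi + 1:05d}_{j + 1}"
        for gi, k in enumerate(probes_per_gene)
        for j in range(k)
    ]

    shift = np.zeros(n_genes)
    for g, f in truth.affected_fold.items():
        shift[gene_ids.index(g)] = np.log2(f)

    samples = _sample_sheet(config)
    is_mut = (samples["group"] == "mutant").to_numpy()
    probe_offset = rng.normal(0.0, config.probe_offset_sd, size=n_probes)
    mean = (
        baseline[gene_of_probe][:, None]
        + probe_offset[:, None]
        + np.outer(shift[gene_of_probe], is_mut.astype(float))
    )
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    matrix = pd.DataFrame(values, index=probe_ids, columns=samples.index)
    matrix.index.name = "probe_id"

    relations: dict[str, set[str]] = {
        pid: {gene_ids[g]} for pid, g in zip(probe_ids, gene_of_probe)
    }
    n_multi = int(round(config.multi_map_fraction * n_probes))
    if n_multi and n_genes > 1:
        multi = rng.choice(n_probes, size=n_multi, replace=False)
        for pi in multi:
            own = gene_of_probe[pi]
            other = int(rng.integers(0, n_genes - 1))
            if other >= own:
                other += 1
            relations[probe_ids[pi]].add(gene_ids[other])
    return matrix, samples, relations


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    n = config.n_samples_per_group
    rows = [(f"wt_{i + 1}", "wt", "F") for i in range(n)] + [
        (f"mut_{i + 1}", "mutant", "F") for i in range(n)
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "group", "sex"]).set_index("sample_id")
    return df


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------


def generate_repeats(
    annotation: GeneAnnotationSet,
    truth: TruthTable,
    config: SimulationConfig,
) -> RepeatAnnotationSet:
    """Poisson repeat placement, with extra density inside planted clusters.

    All families are placed homogeneously at ``background_repeat_density``
    elements/Mb genome-wide; enriched families receive additional elements
    inside each planted cluster span at (factor - 1) x background density,
    topped up (when the factor exceeds 1) so every planted cluster holds
    at least one element of every enriched family.
    """
    config.validate()
    rng = np.random.default_rng(_substream(config.seed, "repeats"))
    chrom = config.chrom
    length = annotation.chrom_lengths.get(chrom, config.chrom_length_bp)
    density = config.background_repeat_density / 1e6  # per bp
    elements: list[tuple[str, GenomicInterval]] = []

    def _place(family: str, lo: int, hi: int, n: int) -> None:
        if n <= 0 or hi <= lo:
            return
        starts = rng.integers(lo, hi, size=n)
        lens = rng.integers(100, 301, size=n)
        for s, ln in zip(starts, lens):
            end = min(int(s) + int(ln), length)
            if end > s:
                elements.append((family, GenomicInterval(chrom, int(s), end)))

    families = tuple(config.background_families) + tuple(config.enriched_families)
    for fam in families:
        _place(fam, 0, length, rng.poisson(density * length))
    extra_rate = (config.enrichment_factor - 1.0) * density
    for fam in config.enriched_families:
        for span in truth.cluster_spans:
            n_extra = rng.poisson(extra_rate * span.length)
            _place(fam, span.start, span.end, n_extra)
    # guarantee: >=1 element of each enriched family per planted cluster.
    # Only under genuine enrichment - at factor 1 the "enriched" families
    # must stay statistically indistinguishable from the background ones.
    for fam in config.enriched_families if config.enrichment_factor > 1 else ():
        for span in truth.cluster_spans:
            if not any(
                f == fam and iv.start < span.end and span.start < iv.end
                for f, iv in elements
            ):
                _place(fam, span.start, max(span.start + 1, span.end - 300), 1)
    elements.sort(key=lambda e: (e[1].chrom, e[1].start, e[0]))
    return RepeatAnnotationSet(elements=elements)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconSpec:
    """One bisulfite amplicon: unit count and per-group mean %, between-embryo sd."""

    amplicon_id: str
    n_units: int
    wt_mean: float
    mut_mean: float
    between_sd: float = 5.0
    unit_sd: float = 2.0

    def validate(self) -> None:
        for m in (self.wt_mean, self.mut_mean):
            if not 0.0 <= m <= 100.0:
                raise ConfigurationError(f"{self.amplicon_id}: mean {m} outside [0,100]")
        if self.n_units < 1:
            raise ConfigurationError(f"{self.amplicon_id}: need >= 1 CpG unit")


#: uniparental-type panel: ~30-50% methylated in wt, hypomethylated in mutant
DEFAULT_METHYLATION_PANEL = (
    AmpliconSpec("DMR_A", 8, 35.0, 15.0),
    AmpliconSpec("DMR_B", 10, 40.0, 20.0),
    AmpliconSpec("DMR_C", 6, 45.0, 25.0),
    AmpliconSpec("DMR_D", 12, 50.0, 30.0),
)


def generate_methylation(
    panel: Sequence[AmpliconSpec],
    groups: Sequence[tuple[str, str]],
    seed: int,
) -> pd.DataFrame:
    """Per-embryo per-CpG-unit percent methylation, truncated to [0,100].

    ``groups`` lists (sample_id, group). Each embryo draws an amplicon-level
    mean from Normal(group mean, between_sd); units scatter around it with
    ``unit_sd``. Returns a tidy table (amplicon_id, sample_id, group,
    unit_index, pct).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in panel:
        spec.validate()
        for sample_id, group in groups:
            mu = spec.wt_mean if group == "wt" else spec.mut_mean
            if spec.between_sd > 0:
                lo, hi = (0.0 - mu) / spec.between_sd, (100.0 - mu) / spec.between_sd
                embryo_mean = float(
                    stats.truncnorm.rvs(lo, hi, loc=mu, scale=spec.between_sd, random_state=rng)
                )
            else:
                embryo_mean = mu
            if spec.unit_sd > 0:
                lo_u = (0.0 - embryo_mean) / spec.unit_sd
                hi_u = (100.0 - embryo_mean) / spec.unit_sd
                units = stats.truncnorm.rvs(
                    lo_u, hi_u, loc=embryo_mean, scale=spec.unit_sd,
                    size=spec.n_units, random_state=rng,
                )
            else:
                units = np.full(spec.n_units, embryo_mean)
            for u, pct in enumerate(units):
                rows.append((spec.amplicon_id, sample_id, group, u, float(pct)))
    return pd.DataFrame(
        rows, columns=["amplicon_id", "sample_id", "group", "unit_index", "pct"]
    )


def generate_clones(
    reference: str,
    n_clones: int,
    p_methylated: float,
    seed: int,
    conversion_rate: float = 1.0,
) -> list[tuple[str, str]]:
    """In-silico bisulfite clones of a reference amplicon.

    Each CpG cytosine stays C with probability ``p_methylated``; every other
    cytosine converts to T with probability ``conversion_rate`` (1.0 = full
    conversion). Returns (clone_id, sequence) pairs.
    """
    if not 0.0 <= p_methylated <= 1.0:
        raise ConfigurationError("p_methylated must be in [0,1]")
    rng = np.random.default_rng(seed)
    ref = reference.upper()
    cpg_c = {i for i in range(len(ref) - 1) if ref[i : i + 2] == "CG"}
    clones = []
    for c in range(n_clones):
        seq = []
        for i, base in enumerate(ref):
            if base != "C":
                seq.append(base)
            elif i in cpg_c:
                seq.append("C" if rng.random() < p_methylated else "T")
            else:
                seq.append("T" if rng.random() < conversion_rate else "C")
        clones.append((f"clone_{c + 1:04d}", "".join(seq)))
    return clones


def random_amplicon(length: int, n_cpg: int, seed: int) -> str:
    """A random ACGT reference sequence containing exactly n_cpg CpG sites."""
    rng = np.random.default_rng(seed)
    if length < 2 * n_cpg:
        raise ConfigurationError("amplicon too short for requested CpG count")
    while True:
        seq = list(rng.choice(list("ATG"), size=length))  # no C outside chosen spots
        pos = sorted(rng.choice(np.arange(0, length - 1, 2), size=n_cpg, replace=False))
        ok = True
        for p in pos:
            seq[p], seq[p + 1] = "C", "G"
        s = "".join(seq)
        if s.count("CG") == n_cpg:
            # add a few non-CpG QC cytosines (not followed by G)
            for i in range(0, length - 1):
                if s[i] == "A" and s[i + 1] != "G" and rng.random() < 0.1:
                    s = s[:i] + "C" + s[i + 1 :]
            if s.count("CG") == n_cpg:
                return s
            ok = False
        if not ok:
            continue


# ---------------------------------------------------------------------------
# Seed plumbing + writers
# ---------------------------------------------------------------------------

_STAGE_LABELS = {
    "genome": 1,
    "expression": 2,
    "repeats": 3,
    "methylation": 4,
    "clones": 5,
    "cluster_test": 6,
    "enrichment": 7,
}


def _substream(root_seed: int, label: str) -> np.random.SeedSequence:
    """Stable per-stage child seed: adding stages never perturbs others."""
    return np.random.SeedSequence(root_seed, spawn_key=(_STAGE_LABELS[label],))


def substream_seed(root_seed: int, label: str) -> int:
    """A plain integer seed (< 2^31) for the given stage substream."""
    return int(_substream(root_seed, label).generate_state(1)[0] % (2**31))


def write_truth(truth: TruthTable, config: SimulationConfig, path: str | Path) -> None:
    """Echo the truth table and config to YAML for provenance."""
    payload = {
        "config": dataclasses.asdict(config),
        "affected_fold": {g: float(f) for g, f in sorted(truth.affected_fold.items())},
        "clusters": [sorted(c) for c in truth.clusters],
        "cluster_spans": [
            {"chrom": s.chrom, "start": s.start, "end": s.end} for s in truth.cluster_spans
        ],
        "enriched_families": list(truth.enriched_families),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def write_expression(
    matrix: pd.DataFrame, samples: pd.DataFrame, relations: dict[str, set[str]],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    matrix.to_csv(outdir / "expression.tsv", sep="\t")
    samples.to_csv(outdir / "samples.tsv", sep="\t")
    with open(outdir / "probe_map.tsv", "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for pid in matrix.index:
            for g in sorted(relations.get(pid, ())):
                fh.write(f"{pid}\t{g}\n")
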