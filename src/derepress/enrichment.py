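"""Repeat-family enrichment inside gene clusters vs size-matched regions.

A family is a candidate only if it occurs at least once in every cluster.
For each candidate, the observed sample is the per-cluster element count
and the null sample pools the counts from n_iter draws of random regions
of identical sizes from the same chromosome. Significance is a one-sided
Wilcoxon rank-sum (observed > null): exact enumeration (a subset-sum
count over mid-ranks, valid under ties) when both samples have <= 12
observations, normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .clustering import GeneCluster
from .core import GenomicInterval, RepeatAnnotationSet

DEFAULT_N_ITER = 1000
EXACT_MAX_N = 12


@dataclass
class EnrichmentResult:
    family: str
    cluster_counts: np.ndarray
    null_counts: np.ndarray
    null_mean: float
    p_wilcoxon: float
    enriched: bool
    n_iter: int
    method: Literal["exact", "normal"]


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def count_family(
    region: GenomicInterval,
    repeats: RepeatAnnotationSet,
    family: str,
    mode: Literal["overlap", "midpoint"] = "overlap",
) -> int:
    """Elements of one family in a region.

    "overlap" counts any half-open intersection (an element straddling
    the boundary counts); "midpoint" counts elements whose midpoint falls
    inside, which partitions counts exactly over a tiling.
    """
    n = 0
    for fam, iv in repeats.elements:
        if fam != family or iv.chrom != region.chrom:
            continue
        if mode == "overlap":
            n += iv.start < region.end and region.start < iv.end
        else:
            n += region.start <= iv.midpoint < region.end
    return int(n)


class _FamilyIndex:
    """Sorted start/end arrays per family for vectorized region counting."""

    def __init__(self, repeats: RepeatAnnotationSet, chrom: str):
        self.by_family: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list[tuple[int, int]]] = {}
        for fam, iv in repeats.elements:
            if iv.chrom == chrom:
                buckets.setdefault(fam, []).append((iv.start, iv.end))
        for fam, pairs in buckets.items():
            starts = np.sort(np.array([p[0] for p in pairs], dtype=np.int64))
            ends = np.sort(np.array([p[1] for p in pairs], dtype=np.int64))
            self.by_family[fam] = (starts, ends)

    def count(self, family: str, region_starts: np.ndarray, region_ends: np.ndarray) -> np.ndarray:
        """Overlap counts for many [start, end) regions at once.

        count = #elements - #(element.end <= region.start) - #(element.start >= region.end)
        which is exact because elements overlapping the region are exactly
        those excluded from both one-sided tallies.
        """
        if family not in self.by_family:
            return np.zeros(len(region_starts), dtype=np.int64)
        starts, ends = self.by_family[family]
        n = len(starts)
        before = np.searchsorted(ends, region_starts, side="right")
        after = n - np.searchsorted(starts, region_ends, side="left")
        return n - before - after


def candidate_families(
    clusters: Sequence[GeneCluster], repeats: RepeatAnnotationSet
) -> list[str]:
    """Families present at least once in every cluster span."""
    if not clusters:
        raise ValueError("need at least one cluster")
    chrom = clusters[0].span.chrom
    index = _FamilyIndex(repeats, chrom)
    starts = np.array([c.span.start for c in clusters], dtype=np.int64)
    ends = np.array([c.span.end for c in clusters], dtype=np.int64)
    return [
        fam
        for fam in sorted(index.by_family)
        if np.all(index.count(fam, starts, ends) >= 1)
    ]


def sample_matched_regions(
    chrom_length: int,
    sizes: Sequence[int],
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Random region starts, one region per size per iterate.

    Returns an (n_iter, len(sizes)) array of start coordinates; region i
    of an iterate has length sizes[i]. Starts are uniform on
    [0, chrom_length - size]; regions may overlap each other.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if np.any(sizes > chrom_length):
        raise ValueError("region size exceeds chromosome length")
    if np.any(sizes < 1):
        raise ValueError("region sizes must be positive")
    rng = np.random.default_rng(seed)
    # integers() high is exclusive; start == chrom_length - size is allowed
    return rng.integers(0, chrom_length - sizes + 1, size=(n_iter, len(sizes)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def exact_ranksum_p_greater(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact one-sided rank-sum p (x tends larger), valid under ties.

    Counts, by dynamic programming over doubled mid-ranks, the subsets of
    size len(x) of the pooled sample whose rank sum is >= the observed
    one; p = count / C(n, len(x)). Matches full enumeration of all rank
    splits of the pooled multiset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks2 = np.round(2.0 * _midranks(np.concatenate([x, y]))).astype(np.int64)
    observed = int(ranks2[:n1].sum())
    total = int(ranks2.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:  # 0/1 knapsack; numpy buffers the overlapping slices
        dp[1 : n1 + 1, r:] += dp[0:n1, : total - r + 1]
    count = float(dp[n1, observed:].sum())
    return count / comb(n, n1)


def ranksum_p_greater(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> tuple[float, Literal["exact", "normal"]]:
    """One-sided Wilcoxon rank-sum p-value that x tends larger than y.

    Exact when both samples have <= exact_max_n observations, else the
    tie-corrected normal approximation (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return exact_ranksum_p_greater(x, y), "exact"
    p = float(
        stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic",
                           use_continuity=False).pvalue
    )
    return p, "normal"


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def stratified_ranksum_p_greater(
    observed: np.ndarray, null_by_stratum: np.ndarray
) -> float:
    """One-sided stratified rank test (van Elteren-style), one observed per stratum.

    Within stratum i the observed count is ranked among its own size-matched
    null counts; the standardized sum of within-stratum mid-ranks is compared
    to its exchangeability null (tie-corrected variance). Exact under the
    stratified null where each cluster is exchangeable only with regions of
    its own size, which the pooled test is not.
    """
    observed = np.asarray(observed, dtype=float)
    n_strata, b = null_by_stratum.shape[0], null_by_stratum.shape[1]
    if len(observed) != n_strata:
        raise ValueError("one observed value per stratum required")
    w = e = v = 0.0
    for i in range(n_strata):
        pooled = np.concatenate([[observed[i]], null_by_stratum[i]])
        ranks = _midranks(pooled)
        n = b + 1
        w += ranks[0]
        e += (n + 1) / 2.0
        _, t = np.unique(pooled, return_counts=True)
        tie = float(np.sum(t**3 - t)) / (n * (n - 1)) if n > 1 else 0.0
        v += (b / 12.0) * ((n + 1) - tie)
    if v <= 0:
        return 1.0
    return float(stats.norm.sf((w - e) / np.sqrt(v)))


def enrichment_test(
    clusters: Sequence[GeneCluster],
    repeats: RepeatAnnotationSet,
    family: str,
    chrom_length: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
    mode: Literal["pooled", "stratified"] = "pooled",
) -> EnrichmentResult:
    """Per-cluster counts vs matched random-region counts, one-sided.

    "pooled" (default, the classical procedure): Wilcoxon rank-sum of the
    per-cluster counts against all region counts pooled across cluster
    sizes. With clusters of unequal sizes the pooled null is a mixture and
    the test is conservative. "stratified" compares each cluster only with
    regions of its own size (van Elteren-style), which restores nominal
    type-I error under size heterogeneity.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    chrom = clusters[0].span.chrom
    index = _FamilyIndex(repeats, chrom)
    if family not in index.by_family:
        raise ValueError(f"family {family!r} absent from the repeat annotation")
    sizes = [c.span.length for c in clusters]
    cl_starts = np.array([c.span.start for c in clusters], dtype=np.int64)
    cl_ends = np.array([c.span.end for c in clusters], dtype=np.int64)
    observed = index.count(family, cl_starts, cl_ends)
    region_starts = sample_matched_regions(chrom_length, sizes, n_iter, seed)
    flat_starts = region_starts.ravel()
    flat_ends = flat_starts + np.tile(np.asarray(sizes, dtype=np.int64), n_iter)
    null = index.count(family, flat_starts, flat_ends)
    if mode == "stratified":
        by_stratum = null.reshape(n_iter, len(sizes)).T  # (stratum, iterate)
        p, method = stratified_ranksum_p_greater(observed, by_stratum), "normal"
    else:
        p, method = ranksum_p_greater(observed, null)
    return EnrichmentResult(
        family=family,
        cluster_counts=observed,
        null_counts=null,
        null_mean=float(np.mean(null)),
        p_wilcoxon=p,
        enriched=bool(p <= alpha),
        n_iter=n_iter,
        method=method,
    )


def enrichment_screen(
    clusters: Sequence[GeneCluster],
    repeats: RepeatAnnotationSet,
    chrom_length: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every candidate family; report all p-values, flag at alpha."""
    families = candidate_families(clusters, repeats)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(families))
    return [
        enrichment_test(clusters, repeats, fam, chrom_length, n_iter, child, alpha)
        for fam, child in zip(families, children)
    ]
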