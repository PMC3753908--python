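import itertools

import numpy as np
import pytest
from scipy import stats

from derepress.clustering import GeneCluster, detect_clusters
from derepress.core import GenomicInterval, RepeatAnnotationSet
from derepress.enrichment import (
    candidate_families,
    count_family,
    enrichment_screen,
    enrichment_test,
    exact_ranksum_p_greater,
    ranksum_p_greater,
    sample_matched_regions,
    stratified_ranksum_p_greater,
)
from derepress.simulate import (
    SimulationConfig,
    generate_genome,
    generate_repeats,
    substream_seed,
)


def repset(elements):
    return RepeatAnnotationSet(
        elements=[(fam, GenomicInterval("chrX", s, e)) for fam, s, e in elements]
    )


def cluster(start, end):
    return GeneCluster(members=["a", "b"], span=GenomicInterval("chrX", start, end),
                       n_genes=2)


class TestCountFamily:
    def test_examples(self):
        reps = repset([("F", 50, 60), ("F", 200, 210)])
        region = GenomicInterval("chrX", 0, 100)
        assert count_family(region, reps, "F") == 1
        assert count_family(region, reps, "absent") == 0

    def test_boundary_straddler_counts_in_overlap_mode(self):
        reps = repset([("F", 90, 110)])
        region = GenomicInterval("chrX", 0, 100)
        assert count_family(region, reps, "F", mode="overlap") == 1
        # midpoint = (90+110)//2 = 100, outside [0,100) -> belongs to the next tile
        assert count_family(region, reps, "F", mode="midpoint") == 0
        assert count_family(GenomicInterval("chrX", 100, 200), reps, "F", "midpoint") == 1

    def test_partition_conservation(self, rng):
        starts = rng.integers(0, 9_800, size=200)
        reps = repset([("F", int(s), int(s) + 150) for s in starts])
        tiles = [GenomicInterval("chrX", i, i + 1000) for i in range(0, 10_000, 1000)]
        overlap_total = sum(count_family(t, reps, "F", "overlap") for t in tiles)
        midpoint_total = sum(count_family(t, reps, "F", "midpoint") for t in tiles)
        assert overlap_total >= len(reps)  # straddlers counted at least once
        assert midpoint_total == len(reps)  # midpoints partition exactly


class TestCandidateFamilies:
    def test_every_cluster_rule(self):
        clusters = [cluster(0, 100), cluster(200, 300), cluster(400, 500)]
        reps = repset(
            [("keep", 10, 20), ("keep", 210, 220), ("keep", 410, 420),
             ("drop", 10, 20), ("drop", 210, 220)]
        )
        assert candidate_families(clusters, reps) == ["keep"]

    def test_no_repeats_gives_empty(self):
        assert candidate_families([cluster(0, 100)], repset([])) == []

    def test_empty_cluster_list_is_error(self):
        with pytest.raises(ValueError):
            candidate_families([], repset([]))


class TestSampleMatchedRegions:
    def test_forced_placement(self):
        starts = sample_matched_regions(1000, [1000], n_iter=5, seed=1)
        assert np.all(starts == 0)

    def test_deterministic(self):
        a = sample_matched_regions(10_000, [100, 200], n_iter=10, seed=2)
        b = sample_matched_regions(10_000, [100, 200], n_iter=10, seed=2)
        assert np.array_equal(a, b)

    def test_uniform_mean(self):
        starts = sample_matched_regions(1_000_000, [1000], n_iter=10_000, seed=3)
        expected = (1_000_000 - 1000) / 2
        se = starts.std(ddof=1) / np.sqrt(starts.size)
        assert abs(starts.mean() - expected) < 3 * se

    def test_oversized_region_rejected(self):
        with pytest.raises(ValueError):
            sample_matched_regions(100, [101], seed=1)


class TestExactWilcoxon:
    def test_complete_separation_three_vs_three(self):
        # all C(6,3)=20 rank splits; only one reaches the observed rank sum
        assert exact_ranksum_p_greater([5, 6, 7], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_identical_multisets_centre(self):
        p = exact_ranksum_p_greater([1, 2, 3], [1, 2, 3])
        assert 0.3 < p <= 0.8

    def brute_force(self, x, y):
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1 = len(x)
        observed = ranks[:n1].sum()
        hits = total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            total += 1
            hits += ranks[list(combo)].sum() >= observed - 1e-9
        return hits / total

    def test_matches_enumeration_oracle_small_samples(self, rng):
        """Exact p equals full rank-split enumeration for n1+n2 <= 10."""
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 5), (2, 8), (3, 7)]:
            for _ in range(3):
                x = rng.integers(0, 6, size=n1)  # small ints force ties
                y = rng.integers(0, 6, size=n2)
                assert exact_ranksum_p_greater(x, y) == pytest.approx(
                    self.brute_force(x, y)
                ), (x, y)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            ours = exact_ranksum_p_greater(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.integers(0, 5, size=9)
        y = rng.integers(0, 5, size=500)
        p, method = ranksum_p_greater(x, y)
        assert method == "normal" and 0 < p <= 1


class TestEnrichmentTest:
    def _world(self, seed, factor=10.0):
        cfg = SimulationConfig(seed=seed, enrichment_factor=factor)
        ann, truth = generate_genome(cfg)
        reps = generate_repeats(ann, truth, cfg)
        clusters, _ = detect_clusters(sorted(truth.affected_genes), ann)
        return cfg, clusters, reps

    def test_planted_families_recovered_exactly(self):
        """On ground-truth clusters the screen flags the two planted SINEs."""
        cfg, clusters, reps = self._world(seed=0)
        results = enrichment_screen(
            clusters, reps, cfg.chrom_length_bp, n_iter=1000,
            seed=substream_seed(0, "enrichment"), alpha=1e-3,
        )
        flagged = sorted(r.family for r in results if r.enriched)
        assert flagged == ["B2_Mm1a", "ID4"]
        assert all(r.p_wilcoxon > 0 for r in results)

    def test_unknown_family_rejected(self):
        cfg, clusters, reps = self._world(seed=1)
        with pytest.raises(ValueError, match="absent"):
            enrichment_test(clusters, reps, "nope", cfg.chrom_length_bp, 10, 1)

    def test_factor_one_rarely_flags_at_strict_alpha(self):
        """Null calibration: no planted enrichment, alpha 1e-3."""
        false_flags = 0
        for seed in range(40):
            cfg, clusters, reps = self._world(seed=200 + seed, factor=1.0)
            for fam in cfg.enriched_families:
                r = enrichment_test(clusters, reps, fam, cfg.chrom_length_bp,
                                    n_iter=300, seed=seed, alpha=1e-3)
                false_flags += r.enriched
        assert false_flags <= 2  # 80 null tests at alpha 1e-3

    def test_stratified_mode_reports_sane_p(self):
        cfg, clusters, reps = self._world(seed=2)
        r = enrichment_test(clusters, reps, "B2_Mm1a", cfg.chrom_length_bp,
                            n_iter=300, seed=5, mode="stratified")
        assert r.p_wilcoxon < 1e-3  # planted 10x enrichment

    def test_screen_reports_every_candidate(self):
        cfg, clusters, reps = self._world(seed=3)
        results = enrichment_screen(clusters, reps, cfg.chrom_length_bp,
                                    n_iter=200, seed=4)
        assert [r.family for r in results] == candidate_families(clusters, reps)


def test_stratified_ranksum_matches_uniform_rank_logic(rng):
    # single stratum, no ties: p should equal the observed value's tail rank share
    null = rng.permutation(np.arange(1, 100, dtype=float))
    p_top = stratified_ranksum_p_greater(np.array([1000.0]), null[None, :])
    p_bottom = stratified_ranksum_p_greater(np.array([-5.0]), null[None, :])
    assert p_top < 0.05 and p_bottom > 0.9
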