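import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from derepress.diffexpr import (
    ExpressionMatrix,
    ProbeStat,
    aggregate_genes,
    bh_adjust,
    classify_probes,
    fit_variance_prior,
    moderated_t,
    percent_change,
    qpcr_relative_expression,
)
from derepress.probemap import ProbeGeneMap


def matrix_from(wt_rows, mut_rows, probe_ids=None):
    wt = np.atleast_2d(np.asarray(wt_rows, dtype=float))
    mut = np.atleast_2d(np.asarray(mut_rows, dtype=float))
    n1, n2 = wt.shape[1], mut.shape[1]
    cols = [f"wt_{i}" for i in range(n1)] + [f"mut_{i}" for i in range(n2)]
    values = pd.DataFrame(np.hstack([wt, mut]), columns=cols)
    values.index = probe_ids or [f"p{i}" for i in range(len(values))]
    samples = pd.DataFrame(
        {"group": ["wt"] * n1 + ["mutant"] * n2, "sex": "F"}, index=cols
    )
    return ExpressionMatrix(values=values, samples=samples)


def pooled_t_oracle(wt, mut):
    """Textbook pooled-variance two-sample t (independent re-derivation)."""
    wt, mut = np.asarray(wt, float), np.asarray(mut, float)
    n1, n2 = len(wt), len(mut)
    sp2 = ((n1 - 1) * np.var(wt, ddof=1) + (n2 - 1) * np.var(mut, ddof=1)) / (n1 + n2 - 2)
    return (mut.mean() - wt.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestModeratedT:
    def test_hand_computed_pooled_t(self):
        m = matrix_from([[1, 2, 3]], [[2, 3, 4]])
        (s,) = moderated_t(m, shrinkage="off")
        assert s.log2fc == pytest.approx(1.0)
        assert s.t == pytest.approx(1.2247, abs=1e-4)  # 1 / sqrt(1*(1/3+1/3))
        assert s.df == 4

    def test_identical_groups_give_t0_p1(self):
        m = matrix_from([[1, 2, 3]], [[1, 2, 3]])
        (s,) = moderated_t(m, shrinkage="off")
        assert (s.t, s.p) == (0.0, 1.0)

    def test_infinite_prior_limit(self):
        # zero-variance data with the posterior pinned at s0^2 = 1
        m = matrix_from([[1, 1, 1]], [[2, 2, 2]])
        (s,) = moderated_t(m, shrinkage="on", prior_df=1e12, prior_var=1.0)
        assert s.t == pytest.approx(1.0 / math.sqrt(2 / 3), abs=1e-4)

    def test_matches_pooled_oracle_on_random_matrices(self, rng):
        wt = rng.normal(6, 1, size=(50, 3))
        mut = rng.normal(6, 1, size=(50, 4))
        stats_ = moderated_t(matrix_from(wt, mut), shrinkage="off")
        for i, s in enumerate(stats_):
            assert s.t == pytest.approx(pooled_t_oracle(wt[i], mut[i]), abs=1e-12)
            assert s.df == 5

    def test_zero_variance_without_shrinkage_warns_p0(self, caplog):
        m = matrix_from([[1, 1, 1]], [[2, 2, 2]])
        with caplog.at_level("WARNING", logger="derepress"):
            (s,) = moderated_t(m, shrinkage="off")
        assert s.p == 0.0 and math.isinf(s.t)
        assert any("zero pooled variance" in r.message for r in caplog.records)

    def test_too_few_samples_rejected(self):
        m = matrix_from([[1, 2]], [[3]])
        with pytest.raises(ValueError, match="2 samples"):
            moderated_t(m)

    def test_shrinkage_pulls_extreme_variances_together(self, rng):
        wt = rng.normal(0, 1, size=(200, 3))
        mut = rng.normal(0, 1, size=(200, 3))
        raw = moderated_t(matrix_from(wt, mut), shrinkage="off")
        mod = moderated_t(matrix_from(wt, mut), shrinkage="on")
        # moderation increases degrees of freedom and damps the largest |t|
        assert mod[0].df > raw[0].df
        assert max(abs(s.t) for s in mod) < max(abs(s.t) for s in raw)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
@pytest.mark.parametrize("heteroscedastic", [False, True], ids=["common-var", "invchisq-var"])
def test_moderated_t_matches_limma_cross_check(tmp_path, rng, heteroscedastic):
    """Independent oracle: the empirical-Bayes fit agrees with limma's eBayes."""
    if heteroscedastic:  # true variances from a scaled inverse chi-square prior
        sd = np.sqrt(0.5 * 6.0 / rng.chisquare(6.0, size=120))
    else:
        sd = np.ones(120)
    wt = rng.normal(5, sd[:, None], size=(120, 3))
    mut = rng.normal(5, sd[:, None], size=(120, 3))
    mut[:20] += 1.0
    m = matrix_from(wt, mut)
    m.values.to_csv(tmp_path / "expr.tsv", sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
        design <- cbind(1, c(rep(0,3), rep(1,3)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], dftotal=fit$df.prior + fit$df.residual,
                          s2post=fit$s2.post)
        write.table(out, commandArgs(TRUE)[2], sep="\t", quote=FALSE)
        """
    )
    out = tmp_path / "limma.tsv"
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(tmp_path / "expr.tsv"), str(out)],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(out, sep="\t")
    ours = moderated_t(m, shrinkage="on")
    assert np.allclose([s.t for s in ours], ref["t"], rtol=1e-6)
    if np.isfinite(ref["dftotal"]).all():
        assert np.allclose([s.df for s in ours], ref["dftotal"], rtol=1e-4)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.5, 0.001], [0.5, 0.002]),
        ],
    )
    def test_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=200)
        q = np.array(bh_adjust(p))
        assert np.all(q <= 1.0) and np.all(q >= p.min() * 0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassify:
    def make(self, actual_change, p):
        lfc = math.log2(actual_change)
        return ProbeStat("p", lfc, actual_change, 0.0, 4, p)

    def test_relaxed_up_25_percent(self):
        s = self.make(1.25, 0.2)
        classify_probes([s])
        assert (s.category, s.direction) == ("relaxed", "up")
        assert percent_change(s.actual_change) == pytest.approx(25.0)

    def test_stringent_down(self):
        s = self.make(0.8, 0.05)
        classify_probes([s])
        assert (s.category, s.direction) == ("stringent", "down")

    def test_above_relaxed_threshold_is_none(self):
        s = self.make(1.9, 0.31)
        classify_probes([s])
        assert (s.category, s.direction) == ("none", "none")

    def test_change_of_exactly_one_has_no_direction(self):
        s = ProbeStat("p", 0.0, 1.0, 0.0, 4, 0.001)
        classify_probes([s])
        assert s.category == "stringent" and s.direction == "none"

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            classify_probes([self.make(1.2, 0.1)], fdr_stringent=0.3, fdr_relaxed=0.1)


class TestAggregateGenes:
    def stat(self, pid, direction, change):
        s = ProbeStat(pid, math.log2(change), change, 0.0, 4, 0.0)
        s.direction = direction
        s.category = "relaxed" if direction != "none" else "none"
        return s

    def umap(self, probes_to_gene):
        return ProbeGeneMap(relations={p: {g} for p, g in probes_to_gene.items()})

    def test_mean_of_upregulated_probes(self):
        stats_ = [self.stat("a", "up", 1.2), self.stat("b", "up", 1.6)]
        (call,) = aggregate_genes(stats_, self.umap({"a": "g", "b": "g"}))
        assert call.status == "upregulated"
        assert call.expression_value == pytest.approx(1.4)

    def test_conflicting_directions(self):
        stats_ = [self.stat("a", "up", 1.5), self.stat("b", "down", 0.7)]
        (call,) = aggregate_genes(stats_, self.umap({"a": "g", "b": "g"}))
        assert call.status == "conflicted"

    def test_no_significant_probe_is_no_change(self):
        stats_ = [self.stat("a", "none", 1.5)]
        (call,) = aggregate_genes(stats_, self.umap({"a": "g"}))
        assert call.status == "no_change"

    def test_probe_absent_from_map_skipped(self, caplog):
        stats_ = [self.stat("a", "up", 1.5), self.stat("zz", "up", 2.0)]
        with caplog.at_level("INFO", logger="derepress"):
            calls = aggregate_genes(stats_, self.umap({"a": "g"}))
        assert len(calls) == 1

    def test_exhaustive_truth_table_oracle(self):
        """All direction combinations for up to 3 probes per gene."""
        def oracle(directions):
            ups, downs = directions.count("up"), directions.count("down")
            if ups and not downs:
                return "upregulated"
            if downs and not ups:
                return "downregulated"
            if ups and downs:
                return "conflicted"
            return "no_change"

        for k in (1, 2, 3):
            for combo in itertools.product(["up", "down", "none"], repeat=k):
                stats_ = [
                    self.stat(f"p{i}", d, 1.5 if d == "up" else 0.7 if d == "down" else 1.0)
                    for i, d in enumerate(combo)
                ]
                (call,) = aggregate_genes(
                    stats_, self.umap({f"p{i}": "g" for i in range(k)})
                )
                assert call.status == oracle(list(combo)), combo


class TestQPCR:
    def ct_table(self, data, samples):
        return pd.DataFrame(data, index=samples)

    def groups(self, samples):
        return pd.Series(["wt"] * 3 + ["mut"] * 3, index=samples)

    def test_target_equal_to_housekeeping_is_unity(self):
        samples = [f"s{i}" for i in range(6)]
        ct = self.ct_table({"hk": [20.0] * 6, "tgt": [20.0] * 6}, samples)
        res = qpcr_relative_expression(ct, ["hk"], self.groups(samples))
        assert res.loc["tgt", "mean_wt"] == pytest.approx(1.0)
        assert res.loc["tgt", "mean_mut"] == pytest.approx(1.0)

    def test_one_cycle_lower_is_twofold(self):
        samples = [f"s{i}" for i in range(6)]
        ct = self.ct_table(
            {"hk": [20.0] * 6, "tgt": [22.0, 22.1, 21.9, 21.0, 21.1, 20.9]}, samples
        )
        res = qpcr_relative_expression(ct, ["hk"], self.groups(samples))
        assert res.loc["tgt", "fold_change"] == pytest.approx(2.0, rel=0.01)

    def test_identical_groups_not_significant(self):
        samples = [f"s{i}" for i in range(6)]
        ct = self.ct_table({"hk": [20.0] * 6, "tgt": [21.0] * 6}, samples)
        res = qpcr_relative_expression(ct, ["hk"], self.groups(samples))
        assert res.loc["tgt", "p"] == 1.0 and not res.loc["tgt", "significant"]

    def test_missing_ct_drops_sample(self, caplog):
        samples = [f"s{i}" for i in range(6)]
        ct = self.ct_table(
            {"hk": [20.0] * 6, "tgt": [21.0, np.nan, 21.0, 20.0, 20.0, 20.0]}, samples
        )
        with caplog.at_level("WARNING", logger="derepress"):
            res = qpcr_relative_expression(ct, ["hk"], self.groups(samples))
        assert res.loc["tgt", "t"] == res.loc["tgt", "t"]  # still testable (2 vs 3)

    def test_requires_housekeeping(self):
        samples = [f"s{i}" for i in range(6)]
        ct = self.ct_table({"tgt": [21.0] * 6}, samples)
        with pytest.raises(ValueError, match="housekeeping"):
            qpcr_relative_expression(ct, ["hk"], self.groups(samples))


def test_variance_prior_recovers_known_hyperparameters(rng):
    """Method-of-moments fit on variances drawn from a known prior."""
    d, d0, s0sq = 4, 8.0, 0.25
    sigma2 = s0sq * d0 / rng.chisquare(d0, size=20_000)
    s2 = sigma2 * rng.chisquare(d, size=20_000) / d
    d0_hat, s0_hat = fit_variance_prior(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.15)
    assert s0_hat == pytest.approx(s0sq, rel=0.05)
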