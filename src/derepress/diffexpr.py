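"""Two-group differential expression on a log2 matrix.

The test is a moderated t: per-probe pooled variances are shrunk toward a
prior estimated across all probes by fitting a scaled inverse-chi-square
distribution via method of moments on log sample variances (empirical
Bayes). With shrinkage off the statistic reduces to the textbook
pooled-variance two-sample t, which serves as the closed-form oracle in
tests. P-values are BH-adjusted across the whole matrix jointly, and
probes are classified by FDR (stringent <= 0.10, relaxed <= 0.30) and by
non-log fold change (> 1 up, < 1 down, strict inequalities). Gene calls
follow the aggregation rule: upregulated iff at least one upregulated and
no downregulated probe set at FDR <= 0.30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import logger
from .probemap import ProbeGeneMap

FDR_STRINGENT = 0.10
FDR_RELAXED = 0.30


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensities plus a sample sheet (group, sex)."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")

    def group_columns(self, group: str) -> list[str]:
        members = self.samples.index[self.samples["group"] == group]
        return [c for c in self.values.columns if c in set(members)]

    @classmethod
    def read(cls, matrix_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(values=values, samples=samples)


@dataclass
class ProbeStat:
    probe_id: str
    log2fc: float
    actual_change: float
    t: float
    df: float
    p: float
    fdr: float = math.nan
    category: Literal["stringent", "relaxed", "none"] = "none"
    direction: Literal["up", "down", "none"] = "none"


@dataclass
class GeneCall:
    gene_id: str
    status: Literal["upregulated", "downregulated", "conflicted", "no_change"]
    expression_value: float = math.nan  # mean non-log change over supporting probes
    n_probes: int = 0


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a convex decreasing map)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) across per-probe variances.

    Models s2 ~ s0^2 * F(df, d0): on the log scale,
    e = log(s2) - digamma(df/2) + log(df/2) has mean
    log(s0^2) + log(d0/2) - digamma(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2). Returns (d0, s0sq); d0 may be inf
    when the observed spread is no larger than pure chi-square noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no excess spread beyond chi-square noise: variances look common;
        # the arithmetic mean is then the natural (unbiased) pooled estimate
        return math.inf, float(np.mean(s2[ok]))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    log_s0sq = emean + special.digamma(half_d0) - math.log(half_d0)
    return d0, float(math.exp(log_s0sq))


def moderated_t(
    matrix: ExpressionMatrix,
    shrinkage: Literal["on", "off"] = "on",
    group_a: str = "wt",
    group_b: str = "mutant",
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> list[ProbeStat]:
    """Per-probe two-sided t between genotype groups (b minus a).

    With shrinkage on, per-probe pooled variances are replaced by the
    posterior (d0*s0^2 + d*s^2)/(d0 + d) with d0 + d degrees of freedom;
    (d0, s0^2) come from the method-of-moments fit unless ``prior_df`` /
    ``prior_var`` pin them explicitly (useful for closed-form checks).
    With shrinkage off this is the ordinary pooled-variance t with
    d = n_a + n_b - 2, the closed-form oracle used in tests.
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} vs {n2}")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    diff = b.mean(axis=1) - a.mean(axis=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / d

    if shrinkage == "on":
        if prior_df is not None or prior_var is not None:
            if prior_df is None or prior_var is None:
                raise ValueError("prior_df and prior_var must be given together")
            d0, s0sq = float(prior_df), float(prior_var)
        else:
            d0, s0sq = fit_variance_prior(s2, d)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = 1e6  # effectively known variance
        else:
            s2_post = (d0 * s0sq + d * s2) / (d0 + d)
            df_total = d0 + d
    elif shrinkage == "off":
        s2_post = s2
        df_total = float(d)
    else:
        raise ValueError("shrinkage must be 'on' or 'off'")

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    out: list[ProbeStat] = []
    zero_var = 0
    for i, probe_id in enumerate(matrix.values.index):
        if se[i] == 0.0:
            zero_var += 1
            if diff[i] == 0.0:
                t, p = 0.0, 1.0
            else:
                t = math.inf if diff[i] > 0 else -math.inf
                p = 0.0
        else:
            t = float(diff[i] / se[i])
            p = float(2.0 * stats.t.sf(abs(t), df_total))
        out.append(
            ProbeStat(
                probe_id=str(probe_id),
                log2fc=float(diff[i]),
                actual_change=float(2.0 ** diff[i]),
                t=t,
                df=float(df_total),
                p=p,
            )
        )
    if zero_var:
        logger.warning("%d probes had zero pooled variance; p reported as 0/1", zero_var)
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def classify_probes(
    probe_stats: list[ProbeStat],
    fdr_stringent: float = FDR_STRINGENT,
    fdr_relaxed: float = FDR_RELAXED,
) -> list[ProbeStat]:
    """Fill fdr/category/direction in place (and return the list).

    Direction uses the non-log change with strict inequalities: a probe
    at exactly 1.0 has no direction. A probe with actual change 1.25 at
    FDR <= 0.30 is "25% upregulated".
    """
    if not fdr_stringent <= fdr_relaxed:
        raise ValueError("fdr_stringent must not exceed fdr_relaxed")
    fdrs = bh_adjust([s.p for s in probe_stats])
    for s, q in zip(probe_stats, fdrs):
        s.fdr = float(q)
        if q <= fdr_stringent:
            s.category = "stringent"
        elif q <= fdr_relaxed:
            s.category = "relaxed"
        else:
            s.category = "none"
        if s.category != "none" and s.actual_change > 1.0:
            s.direction = "up"
        elif s.category != "none" and s.actual_change < 1.0:
            s.direction = "down"
        else:
            s.direction = "none"
    return probe_stats


def percent_change(actual_change: float) -> float:
    """Report convention: actual change 1.25 -> 25 (% upregulated)."""
    return (actual_change - 1.0) * 100.0


def aggregate_genes(
    probe_stats: list[ProbeStat], unique_map: ProbeGeneMap
) -> list[GeneCall]:
    """Fold probe calls into gene calls through the uniqueness-filtered map.

    upregulated: >=1 up probe and no down probe (FDR <= relaxed);
    downregulated symmetric; conflicted: both directions; no_change:
    no significant probe. The expression value is the arithmetic mean of
    the non-log changes of the supporting (same-direction) probes.
    """
    by_gene: dict[str, list[ProbeStat]] = {}
    skipped = 0
    for s in probe_stats:
        genes = unique_map.genes_of(s.probe_id)
        if len(genes) != 1:
            skipped += 1
            continue
        by_gene.setdefault(next(iter(genes)), []).append(s)
    if skipped:
        logger.info("%d probe stats not in the unique map; skipped", skipped)

    calls: list[GeneCall] = []
    for gene_id in sorted(by_gene):
        probes = by_gene[gene_id]
        ups = [s for s in probes if s.direction == "up"]
        downs = [s for s in probes if s.direction == "down"]
        if ups and not downs:
            value = float(np.mean([s.actual_change for s in ups]))
            calls.append(GeneCall(gene_id, "upregulated", value, len(probes)))
        elif downs and not ups:
            value = float(np.mean([s.actual_change for s in downs]))
            calls.append(GeneCall(gene_id, "downregulated", value, len(probes)))
        elif ups and downs:
            calls.append(GeneCall(gene_id, "conflicted", math.nan, len(probes)))
        else:
            calls.append(GeneCall(gene_id, "no_change", math.nan, len(probes)))
    return calls


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def qpcr_relative_expression(
    ct_table: pd.DataFrame,
    housekeeping: Sequence[str],
    groups: pd.Series,
    alpha: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Housekeeping-normalized qPCR expression with a per-target group test.

    ``ct_table`` is samples x targets of Ct values. Relative expression is
    2^-(Ct_target - mean housekeeping Ct) per sample; group comparison is a
    two-sided unpaired pooled-variance t, flagged at p <= alpha. Samples
    with a missing Ct are dropped for that target (with a warning).
    """
    hk = [h for h in housekeeping if h in ct_table.columns]
    if not hk:
        raise ValueError("no housekeeping target present in the Ct table")
    hk_ok = ct_table[hk].notna().all(axis=1)
    if not hk_ok.all():
        raise ValueError("every sample needs Ct values for all housekeeping targets")
    hk_mean = ct_table[hk].mean(axis=1)
    group_names = sorted(groups.unique())
    if len(group_names) != 2:
        raise ValueError("qPCR comparison needs exactly two groups")
    if reference is None:  # wild type is the natural baseline when present
        reference = "wt" if "wt" in group_names else group_names[0]
    if reference not in group_names:
        raise ValueError(f"reference group {reference!r} not among {group_names}")
    ga = reference
    gb = next(g for g in group_names if g != ga)
    rows = []
    for target in ct_table.columns:
        if target in hk:
            continue
        rel = 2.0 ** -(ct_table[target] - hk_mean)
        n_missing = int(rel.isna().sum())
        if n_missing:
            logger.warning("%s: dropped %d samples with missing Ct", target, n_missing)
        rel = rel.dropna()
        va = rel[groups.reindex(rel.index) == ga].to_numpy()
        vb = rel[groups.reindex(rel.index) == gb].to_numpy()
        if len(va) >= 2 and len(vb) >= 2:
            t, p = stats.ttest_ind(vb, va, equal_var=True)
            if np.isnan(t):  # both groups constant and equal
                t, p = 0.0, 1.0
        else:
            t, p = math.nan, math.nan
        rows.append(
            {
                "target": target,
                f"mean_{ga}": float(np.mean(va)) if len(va) else math.nan,
                f"sd_{ga}": float(np.std(va, ddof=1)) if len(va) > 1 else math.nan,
                f"mean_{gb}": float(np.mean(vb)) if len(vb) else math.nan,
                f"sd_{gb}": float(np.std(vb, ddof=1)) if len(vb) > 1 else math.nan,
                "fold_change": (
                    float(np.mean(vb) / np.mean(va)) if len(va) and len(vb) else math.nan
                ),
                "t": float(t),
                "p": float(p),
                "significant": bool(p <= alpha) if not math.isnan(float(p)) else False,
            }
        )
    return pd.DataFrame(rows).set_index("target")


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def probe_stats_frame(probe_stats: list[ProbeStat]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in probe_stats]).set_index("probe_id")


def gene_calls_frame(calls: list[GeneCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls]).set_index("gene_id")
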