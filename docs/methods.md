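# Methods

## Scope and model

The pipeline addresses a recurring design in epigenomics: a wild-type vs
mutant comparison where loss of a repressor derepresses the silent allele
of monoallelically expressed genes. Three statistical questions follow:

1. which genes changed, given that a monoallelic→biallelic shift is at
   most 2-fold;
2. whether the affected genes are positionally clustered along the
   chromosome;
3. whether the clusters are enriched for specific repeat families, and
   whether associated CpG islands lose methylation.

All coordinates are 0-based half-open internally; GFF3 is converted at
the I/O boundary. Strand is carried but ignored by every statistic.

## Differential expression

Per probe set, the contrast is mean(mutant) − mean(wt) on the log2 scale.
The test statistic is a moderated t: the pooled per-probe variance s²
(d = n₁ + n₂ − 2 df) is shrunk toward a prior s₀² estimated across all
probes by fitting a scaled inverse-χ² distribution with d₀ prior df,
using method of moments on e = log s² − ψ(d/2) + log(d/2):

- E[e] = log s₀² + log(d₀/2) − ψ(d₀/2),
- Var[e] = ψ′(d/2) + ψ′(d₀/2),

solved by inverting the trigamma function (Newton). The posterior
variance is (d₀s₀² + ds²)/(d₀ + d) with d₀ + d df. When the observed
spread of log-variances does not exceed pure χ² noise, d₀ = ∞ and the
common variance is the arithmetic mean of the s² (the statistic then
behaves as a z-test). This reproduces the behaviour of the standard
empirical-Bayes microarray analysis without copying an implementation;
an independent cross-check against limma's `eBayes` (via Rscript) agrees
to 10⁻⁶ relative tolerance in both the common-variance and finite-prior
regimes. With `shrinkage="off"` the statistic is exactly the textbook
pooled t, which the unit tests verify against the closed form at 1e-12.

BH adjustment (statsmodels, `fdr_bh`) is applied across the whole matrix
jointly. Classification: stringent FDR ≤ 0.10, relaxed FDR ≤ 0.30;
direction from the non-log change with strict inequalities (a change of
exactly 1 has no direction). Gene aggregation: upregulated iff ≥ 1
upregulated and 0 downregulated probe sets at FDR ≤ 0.30 (symmetric for
down; both directions ⇒ conflicted); the gene's expression value is the
arithmetic mean of the non-log changes of the supporting probes — non-log
because reported per-gene overexpression values are conventionally quoted
on the natural (non-log) scale.

qPCR support: relative expression 2^−(Ct_target − mean housekeeping Ct)
per sample (arithmetic mean of housekeeping Ct = geometric mean of linear
abundances), two-sided unpaired pooled t between groups, flag at p ≤ 0.05.

## Positional clustering

Statistic: median of successive start-to-start gaps of the called genes
(gene starts as anchors; midpoints available as an option — the choice is
immaterial for desk-scale gene sizes). Null: k genes resampled uniformly
without replacement from the chromosome's annotated genes (by default the
array-represented subset), n_iter = 1000 iterates. Reported:

- p_empirical = (1 + #{null ≤ observed}) / (n_iter + 1) — the headline,
  assumption-free, floored at 1/(n_iter+1);
- p_parametric — lower-tail probability under a Normal fitted to the null
  medians (the classical "t-test on the null distribution" reading); the
  null median distribution has a long right tail for small k, so this is
  secondary;
- a normal-theory 95% CI for the null mean (mean ± 1.96 sd/√n_iter).

Cluster detection chains position-sorted called genes while successive
start gaps stay ≤ max_gap (default 500 kb, configurable); maximal chains
with ≥ 2 genes become clusters. No chaining rule is canonical in the
literature; max-gap chaining is the simplest rule with one interpretable
parameter.

## Repeat enrichment

Candidate families must appear at least once in every cluster (the strict
screening rule; it deliberately trades recall for specificity, and under
FDR-30% calling noise a spurious two-gene cluster can remove a genuinely
enriched family — see Limitations). Counts use any-overlap semantics
(half-open); a midpoint mode exists which partitions counts exactly over
a tiling.

For each candidate family the observed sample is the per-cluster count;
the null pools counts from n_iter iterates of one random region per
cluster size, placed uniformly (regions may overlap; no exclusion mask).
Test: one-sided Wilcoxon rank-sum (observed > null).

- Exact branch (both samples ≤ 12): the p-value is computed by a
  subset-sum dynamic program over doubled mid-ranks, equivalent to full
  enumeration of rank splits and valid under ties.
- Otherwise: tie-corrected normal approximation (scipy `mannwhitneyu`).

**Calibration caveat.** When cluster sizes differ, each cluster count is
exchangeable only with regions of its own size; pooling sizes makes the
classical rank-sum variance too large and the pooled test conservative
(measured type-I error 0.005 at nominal 0.05). The `stratified` mode
(van Elteren-style: rank each cluster within its own size stratum,
standardize the summed ranks with tie-corrected within-stratum variances)
restores nominal error (measured 0.050). Pooled remains the default
because it is the classical procedure this pipeline mirrors; use
stratified when calibrated type-I error matters.

## Methylation

Per-sample amplicon summary: mean over non-missing CpG units (dropouts
excluded pairwise, never imputed). Group comparison: two-sided unpaired
pooled-variance Student t on per-sample means, requiring ≥ 2 samples per
group (flagged not-testable otherwise); Welch available as a flag.
Order of averaging is units-then-embryos.

Bisulfite clones are assumed pre-aligned (equal length) to the reference
amplicon. At each reference CpG cytosine: C ⇒ methylated, T ⇒
unmethylated, else ambiguous (excluded from numerator and denominator of
summaries). Conversion QC: fraction of non-CpG reference cytosines read
as T; clones under 0.97 are flagged rejected (no threshold is standard in
print; 0.97 is common practice and configurable).

## Synthetic world

The generator's defaults are the stated scenario, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| chromosome | 166,650,296 bp | mouse X, NCBI m37 |
| genes | 569 | X genes represented on a 430 2.0-class array |
| affected fraction | 0.10 (57 genes) | ~10% of X genes derepressed |
| fold range | 1.2–2.0 (uniform) | monoallelic→biallelic ceiling of 2× |
| clusters | 9, of 2–12 genes, spans 65 kb–1.5 Mb | observed cluster inventory |
| clustered fraction | 0.70 of affected genes | ~70% of upregulated probes clustered |
| samples | 3 wt vs 3 mutant | three embryos per genotype |
| noise sd | 0.25 log2 units | free parameter: a 2× shift at n = 3 is detectable but not trivial |
| probes per gene | 1–3 | ~1.9 probe sets/gene on the array |
| repeat background | 5 elements/Mb/family, 10 families | desk-scale rmsk stand-in |
| enrichment factor | 10× inside cluster spans | clearly separated alternative |
| methylation panel | 4 amplicons, wt 35–50%, Δ = −20 points, sd 5, n 3 | uniparental-type DMRs hypomethylated in mutant |

Structural choices: baseline log2 expression ~ Normal(6, 2) truncated at
0 (realistic dynamic range only); per-probe affinity offsets Normal(0,
0.5); a planted cluster's span is coupled to its size (span ≤ (k−1)·300
kb, members evenly spaced with ±30% jitter) so planted clusters are
locally dense objects rather than two genes 1.5 Mb apart; cluster spans
are ≥ 3 Mb apart, and scattered (non-clustered) affected genes stay ≥ 1
Mb from the spans *and from each other* — otherwise the generator would
inject clusters the truth table does not record. Multi-mapping probes
default to 0: the uniqueness filter has exact worked-example oracles, and
the recovery benchmark is meant to isolate statistical power from
annotation artifacts; set `multi_map_fraction > 0` to exercise the filter
end to end. The enriched-family "≥ 1 element per cluster" guarantee is
applied only when the enrichment factor exceeds 1, so factor 1 is an
exact null. The generator does not emulate probe-level microarray
physics, within-chromosome expression trends, or allele-level reads; a
green recovery test therefore establishes correct statistical behaviour
under the stated noise model, not robustness to real-array artifacts.

Seeding: one root seed spawns stable per-stage substreams
(`SeedSequence(root, spawn_key=(stage,))`), so adding a stage never
perturbs earlier stages and a fixed config yields a byte-identical run
report.

## Numerical choices

- Percentages are full-precision internally and rounded half-up to two
  decimals only at report time.
- Median of an even number of gaps: midpoint of the two central values.
- Trigamma inversion: Newton with convex update, 50 iterations, 1e-10
  relative tolerance.
- Ties at non-log change exactly 1: no direction (strict inequalities).
- Zero-variance probes with shrinkage off: p reported as 0 (warning);
  identical groups: t = 0, p = 1.
- Exact Wilcoxon enumeration is used when both samples have ≤ 12 values;
  the DP is O(n₁ · Σranks) and exact under ties.

## Known limitations

- End-to-end recovery is bounded by detection power: at noise sd 0.25 and
  n = 3, probes of genes with fold < ~1.4 have two-sided p ≈ 0.2 and
  cannot clear FDR ≤ 0.30; measured gene-level recall is ≈ 0.85. Planted
  clusters are therefore recovered only partially through the full
  pipeline (per-cluster Jaccard typically 0.6–0.9), and chained false
  positives can create small spurious clusters that strip genuinely
  enriched families of their every-cluster candidacy. Feeding the
  detector the ground-truth affected set recovers every planted cluster
  exactly and flags exactly the planted families — the gap is statistical
  power, not implementation.
- The two-sided pooled t at Δ = 20 points, sd 5, n = 3/group has analytic
  power 0.948 (noncentral t); empirical power measures ≈ 0.944.
- The pooled enrichment mode is conservative under cluster-size
  heterogeneity (above); no multiple-testing correction is applied across
  families by default (raw Wilcoxon p-values are reported; a BH switch
  exists).
- Interval scans are linear (desk-scale inputs); no liftover, no genome
  sequence handling, no TAD/interaction analysis, no indel-tolerant clone
  alignment.
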