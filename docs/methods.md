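# Methods

This note documents the statistical procedures implemented in `mhgpipe`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Preprocessing

**Quantile normalization.** Each sample column is replaced rank-for-rank by
the across-sample mean of order statistics. Ties within a column receive the
mean of the target values over their tied rank span; this keeps the
transform deterministic and idempotent on tie-free data (continuous
intensities are tie-free almost surely; exact idempotence under ties is not
guaranteed by any tie convention). Within-sample rank order is preserved.

**Detection.** A probe is detected when its value strictly exceeds the
threshold in at least one sample. "Exceeds" is read literally as `>`;
the boundary case (value equal to the threshold in every sample) is
undetected, which is asserted in the tests. The detected set is monotone
non-increasing in the threshold. In practice the threshold is chosen by
inspecting the pooled log-intensity distribution; `suggest_threshold`
automates this as a pooled percentile (default 20th) and logs a text
histogram so the choice can still be eyeballed. Percentiles throughout the
package (detection, s0) use linear interpolation between closest order
statistics, the spreadsheet/NumPy default ("type 7"), applied consistently.
The pipeline default is to filter **after** normalization; filtering before
is available via `filter_before_normalization` (the stage order is not
dictated by the math, only by convention — normalizing first keeps the
quantile targets comparable across the full probe complement).

Inputs are assumed to be on the log2 scale already; `log2_transform` applies
log2(x+1) for raw-scale matrices.

## SAM-style differential statistics

For two groups with n₁, n₂ ≥ 2 replicates the per-probe statistic is the
two-class unpaired moderated difference

    d = (x̄₂ − x̄₁) / (s + s0),
    s = sqrt[(1/n₁ + 1/n₂) · (SS₁ + SS₂) / (n₁ + n₂ − 2)],

i.e. the pooled-variance t statistic with a constant s0 added to every
denominator. With s0 = 0 and equal group sizes, d equals the classical
pooled t exactly (tested to 1e−10). s0 — the exchangeability factor — is a
percentile of the per-probe scatter values s, default the 75th: the point of
s0 is to regularize exactly the quantity in the denominator, so the
percentile is taken over s rather than over per-probe standard deviations.

**Permutation null.** Group labels are permuted over samples. When the
number of balanced relabelings C(n₁+n₂, n₁) is at most 2000 they are
enumerated exhaustively (for the default 3+3 design that is 20 relabelings,
identity included); otherwise the configured number of random label
permutations is sampled at a fixed seed. Exhaustive enumeration is used
whenever available because resampling from a 20-element null adds Monte-
Carlo noise without adding information.

**FDR and q-values.** For each threshold δ in a grid (default 50 evenly
spaced values from 0 to max|d|), the called set is {|d| ≥ δ} and

    FDR(δ) = median_b #{|d*_b| ≥ δ} / max(1, #called), capped at 1.

A probe's q-value is the minimum FDR over thresholds at which it is called,
i.e. the prefix-minimum of FDR over δ ≤ |d|; this makes q monotone
non-decreasing as |d| decreases, which is asserted on every run. Per-probe
permutation p-values pool the permuted |d*| over all probes and use add-one
smoothing, p = (b+1)/(B+1), so p is never zero. The output table sorts by q
ascending with ties broken by |d| descending then probe id, making the
ranking deterministic.

**Fold change and reporting filter.** Fold change is 2^(mean log2 treated −
mean log2 control) with treated = the second group declared in the sample
table; a direction flag marks ratios below 1 as "down". The reporting filter
keeps probes with max(ratio, 1/ratio) ≥ 1.2 and p ≤ 0.05, both boundaries
inclusive.

## Rank-order gene-set enrichment

The q-sorted probe table is collapsed to genes: the best-ranked probe per
gene is kept, un-annotated probes are dropped with a logged count, and the
surviving genes are re-ranked 1..N. Gene symbols are the identifier space;
translation tables (e.g. to Entrez) can be applied upstream but no live
mapping service is called.

For a set with n ≥ 1 members in the ranked list, at ascending member ranks
r₁ < … < r_n,

    p_k = P(X_{r_k} ≥ k),  X_r ~ Hypergeometric(N, r, n),

the probability that at least k of n ranks drawn uniformly without
replacement land in the top r_k positions — equivalently the tail of the
k-th order statistic of the drawn ranks. The raw set p-value is min_k p_k
with k* the smallest minimizer. The statistic responds only to
overrepresentation at the top of the ranking; depleted or oddly distributed
sets score near 1.

**Direction convention.** With ranks read as 1 = most significant, "the k-th
best member rank is at least as good as r_k" is the tail that realizes
top-of-list detection; the complementary reading (scoring the bottom of the
list) is available as `variant="literal"`. The default is the top-of-list
tail because that is the stated purpose of the statistic.

**Multiplicity.** The n tails of one set are strongly dependent, so no
within-set adjustment over k is applied. Across sets, Bonferroni multiplies
the raw p by m = the number of *testable* sets (non-empty intersection with
the ranked list — Bonferroni over tests actually performed), capped at 1;
sets are reported at adjusted p ≤ 0.01 and output is sorted by
(adjusted p, name).

**Null behaviour and a known limitation.** min_k p_k is a minimum of
dependent tails and is *not* uniform under the null: its lower tail is
inflated relative to uniform (bounded above by n·t at threshold t, typically
a factor of ~5–15 for n = 10–40). Bonferroni over sets therefore controls
the family-wise error only approximately; occasional false reports at
adjusted p ≤ 0.01 are expected under a pure null, and the test suite
measures exactly this. Methods in the same minimum-hypergeometric family
compute an exact null distribution for the minimum to remove this
inflation; that correction is outside this package's scope, and reported
sets near the α boundary should be read accordingly.

**Numerics.** p_k is computed from log-gamma binomial coefficients with
compensated (`math.fsum`) summation of the hypergeometric terms, clamped to
(0, 1]; agreement with exhaustive subset enumeration is 1e−12 for all
N ≤ 12, n ≤ 4, and with an independent hypergeometric-tail implementation to
1e−9 at large N.

## qPCR quantification

Comparative-Ct with perfect doubling: per sample, ΔCT = CT(target) −
CT(reference); per target, ΔΔCT = mean ΔCT(treated) − mean ΔCT(control) and
RQ = 2^−ΔΔCT (independent groups; no per-sample pairing across groups). The
group test is a classical unpaired, equal-variance, two-sided Student t-test
on per-sample ΔCT values. Dispersion is reported as the SEM of per-sample
relative quantities 2^−(ΔCT − mean ΔCT_control) per group — the RQ scale,
chosen because that is the scale of the plotted bars; the scale is recorded
in the output (`sem_scale`). The default reference gene is GAPDH. Changes
are rendered with the mixed convention used in expression figure legends:
RQ < 1 as percent decrease, 1 ≤ RQ < 2 as percent increase, RQ ≥ 2 as
"x.xx fold" increase.

## Synthetic-data generator

The generator emulates a two-arm (treated vs scramble-control) bead-array
knockdown experiment on the log2 scale:

- per-probe baselines ~ Normal(8, 1.5²) log2 units, the scale of normalized
  bead-array intensities; additive Gaussian measurement noise, sd 0.3,
  independent per observation;
- 3 replicates per arm by default (the scale of small culture experiments;
  configurable upward for power studies — differential statistics require
  ≥ 2);
- 1–3 probes per gene (default distribution 50/30/20%), so the collapsing
  rule is exercised; alternatively an exact probe count can be imposed;
- a fraction (default 10%) of genes differentially expressed, fold drawn
  from {1.2, 1.5, 2.0} — the range typical of modest knockdown signatures —
  with half down-regulated; the group-mean log2 shift equals log2(fold)
  exactly before noise;
- 5% of probes (from non-DE genes) hard-shifted entirely below the
  detection floor (default 5.0 log2 units), making the detection filter's
  effect deterministic and testable;
- 50 gene sets of 10–40 members; enriched sets draw 80% of members from
  true-DE genes, null sets uniformly from all genes;
- qPCR plates with a group-independent reference gene (baseline Ct 18) and
  targets (baseline Ct 26) offset by −log2(RQ) in the treated arm, with
  independent Gaussian well noise (so ΔCT noise is √2 × the per-well sd);
  ct_sd = 0 recovers RQ exactly.

All randomness flows from a single seed, split per stage with
`SeedSequence`; identical configs give byte-identical outputs. Every probe,
gene, set and target has exactly one ground-truth record.

**What it does not emulate** (and what passing tests therefore do not show
about real data): bead-level summarization, background correction,
chip/batch and dye effects, intensity-dependent (heteroskedastic) noise,
probe cross-hybridization, correlated genes within sets beyond the DE spike,
GO-style set overlap/hierarchy, and qPCR efficiency ≠ 2.

## Problem sizes used in validation

The calibration and recovery checks run the full pipeline on 100 simulated
experiments each: null calibration at 1000 probes/1000 genes, 3+3 samples
(20 exhaustive relabelings); spike recovery at 500 genes with a single
enriched set and fold-2 spikes. These sizes give the Monte-Carlo error the
assertions need while keeping the whole suite fast on one CPU.

## Error handling conventions

Configuration errors name the offending field; design errors (a group with
one replicate) are distinguished from malformed-input errors (missing
values, duplicate ids, empty files, truncated GMT lines — reported with line
numbers). Degenerate statistics are defined explicitly: a constant probe
with s0 = 0 has d = 0; a noise-free qPCR contrast has p = 1 when ΔΔCT = 0
and p = 0 otherwise (the t statistic is unbounded there).
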