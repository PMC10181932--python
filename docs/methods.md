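# Methods

`tfdose` analyses titration series in which a transcription factor (TF) is
degraded to a ladder of stable dosages (percent of the unperturbed level)
and chromatin accessibility (ATAC) or expression (RNA) is measured with
several biological replicates per dosage.  This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Dose–response model

For each feature (regulatory element or gene), abundances are prepared as
TMM-normalized CPM, corrected for differentiation batch, scaled by the
maximum absolute value, and cleaned of outlier samples (|z| > 3 on the
corrected, pre-scaling values, single pass).  The cleaned values `y` are
then fitted against dosage `d` with three nested descriptions:

- linear: `y = a·d + b` (least squares);
- **hill2**: with `u(d) = d^h / (ED50^h + d^h)`,

  `y(d) = y_lo + (y_hi − y_lo) · (u(d) − u(d_lo)) / (u(d_hi) − u(d_lo))`

  where `y_lo`/`y_hi` are the condition means at the lowest (full
  depletion) and highest (no depletion) dosages and `d_lo`/`d_hi` those
  dosages; free parameters: ED50 and the Hill exponent `h`;
- **hill3**: the same with `y_hi` free (used when the no-depletion
  condition mean is a poor anchor for the curve's maximum).

The curve *passes through* the fixed minimum and maximum at the anchor
dosages rather than treating them as asymptotes.  This is deliberate: the
extreme-condition means estimate the curve's *values* at those dosages,
and constraining the asymptotes to them instead biases the Hill exponent
upward by 30–40% whenever the response has not saturated inside the
observed range.  With the through-anchor form the noiseless fit recovers
generating parameters exactly, and the estimator is unbiased (median
signed Hill-exponent error a few percent) under realistic noise.

ED50 is the dosage at which the underlying Hill term crosses one half:
low ED50 = buffered (the feature holds its level until the TF is nearly
gone), high ED50 = sensitive.  Features are classified buffered
(ED50 < 30), moderately sensitive (30 ≤ ED50 ≤ 40; both boundaries
assigned to the middle class) or highly sensitive (ED50 > 40).  ED50
estimates above 100 (extrapolated half-points) are allowed and classified
by the same thresholds.

Model selection uses least-squares AIC, `n·ln(RSS/n) + 2k` with `k` free
parameters (constants cancel in differences): hill3 replaces hill2 when
it improves AIC by more than 2, and `ΔAIC = AIC(linear) − AIC(chosen
Hill)` > 2 marks a feature as genuinely sigmoidal.  Parameter p-values
come from the asymptotic covariance of the nonlinear fit; analyses of
fitted ED50/h are restricted to *good fits*, both p < 0.05.

Numerics: bounded nonlinear least squares (ED50 ∈ (0.1, 500),
h ∈ (0.1, 20)) with an analytic Jacobian, multi-started from
ED50 ∈ {20, 50, 80} (ties resolved toward the lowest start by strict RSS
improvement); zero-variance input yields a flagged, non-converged linear
fit rather than an exception; the anchored form's denominator is floored
at 1e-12 where `h → 0` makes it degenerate.

The buffering index at dosage d is
`BI(d) = 100 − 100·(f(100) − f(d))/(f(100) − f(0))` on the fitted curve:
0 means the full TF-dependent change has already occurred by dosage d,
100 means none of it has.  Group summaries use median dosage curves — the
normalized Hill term evaluated at the group median ED50 and exponent.

## Uncertainty: condition-wise bootstrap

Parametric standard errors for ED50/h from nonlinear least squares are
unstable, so uncertainty is estimated by resampling replicates with
replacement *within* each dosage condition (200 resamples by default),
re-applying the outlier mask and scaling, and refitting with the Hill
variant fixed to the full-data choice (so the statistic keeps one
definition across resamples) and the optimizer started from the full-data
estimate.  95% intervals are the 2.5/97.5 percentiles of converged
refits; an envelope with under 50% convergence is flagged unreliable.
Group intervals apply the group statistic (median) across members
separately at each bootstrap index — never by pooling member percentiles —
which preserves the within-resample dependence structure.

## ABC fold-change propagation

A regulatory element's contribution to a gene within 5 Mb of its TSS is
`dist^−0.7 · sqrt(ATAC × H3K27ac)` — a distance power law standing in for
3D contact times the geometric-mean baseline activity — normalized per
gene to sum to 1 (the ABC score).  The gene's own promoter (any RE within
1 kb of the TSS) is excluded, which doubles as the divergence guard at
zero distance; no other distance floor exists.  Predicted gene fold
change at a dosage is the ABC-weighted mean of RE fold changes on the
linear scale (`ΔG = Σ ABC·ΔATAC / Σ ABC`; the denominator matters only
when some REs lack fold changes — predictions using under half of a
gene's ABC mass are flagged low-confidence).  Baseline H3K27ac is assumed
to track ATAC at partial dosages, so only baseline values enter the
scores.  Coordinates are 0-based half-open with RE midpoint to TSS
distances; log-scale averaging of fold changes is a plausible variant we
did not adopt, since the upstream fold changes are linear-scale
estimates.

Stratification normalizes each gene's log fold change at a dosage by its
full-depletion log fold change, bins genes by fitted ED50 (same 30/40
thresholds), and tests bin separation per dosage with Kruskal–Wallis over
bins with at least 3 genes.

## Consensus peaks

Summit positions are merged in two stages: within each replicate,
single-linkage clusters over consecutive sorted gaps ≤ 75 bp are replaced
by their mean position (rounded half-up); across all replicates the same
clustering at 150 bp is applied, and clusters are kept only with summits
from ≥ 3 distinct differentiation/line instances.  Surviving summits are
extended ±250 bp (half-open, clipped at zero) and overlapping or
book-ended regions unioned.  Single linkage resolves the chain ambiguity
("within 75 bp" applied transitively), matching common practice; a
brute-force all-pairs transitive-closure oracle encodes the same rule in
the tests.

## Preprocessing details

TMM scale factors use the sample whose upper quartile of
library-normalized counts is closest to the mean upper quartile as
reference, a 30%/5% double trim on M/A values over features nonzero in
both samples, precision weights, and renormalization to geometric mean 1.
The differential test marking TF-dependent features is deliberately
simple — Welch's t on log2(CPM+1) between the extreme dosages with
Benjamini–Hochberg control — its only contract is FDR control on
synthetic data; it makes no claim to the power of a count-model test.
Batch correction removes per-batch offsets per feature (residuals + grand
mean) on the abundance scale; a batch perfectly confounded with one
dosage condition triggers a warning rather than an error.  The z > 3
outlier rule is applied once, before scaling; applying it to scaled
values instead is exposed as an alternative a caller can implement by
composing the primitives.

## Synthetic data: what it emulates and what it does not

The generator emulates a 6-dosage (100/72/51/36/18/4 percent) ×
7-replicate design: per-feature Hill (either direction), linear or null
mean curves; multiplicative log-normal batch effects per (batch, feature)
with σ = 0.1 log2 units across 4 differentiation batches; negative-
binomial counts (gamma–Poisson, dispersion α = 0.05, so per-sample CV
≈ 22%) at library sizes of 8–12 million; baselines 10–200 CPM; response
amplitudes 4–8 fold; ED50 ∈ (10, 90); Hill exponents ∈ (1, 6).  Defaults
total 2,000 features of which 400 respond — between-sample normalization
sees the mostly-unchanged majority it assumes.  The regulatory
architecture places genes on a 100 Mb contig with REs within ±2 Mb of
their gene's TSS (outside the 1 kb promoter zone); all REs of a gene
share a per-gene base ED50 (± 3 jitter) so genes have coherent
sensitivities, and true gene fold changes are ABC-weighted means over
*all* REs within the 5 Mb window times exp(N(0, σ_gene)) noise.

Not emulated: read-level artifacts (fragment length, Tn5 bias, GC),
dosage-dependent dispersion, correlated features, multi-TSS genes, Hi-C
contact variation, and real batch×condition interactions.  Passing
benchmarks therefore demonstrate correctness and statistical behaviour of
the estimators under the stated noise model, not performance on real
sequencing data.

## Benchmark design and known limitations

The fitting benchmarks (parameter recovery, model selection, bootstrap
coverage) normalize counts by the generator's true library sizes: with
hundreds of strongly responsive features, column-sum or TMM normalization
absorbs a dosage-structured composition shift and would add shared
curvature, conflating normalization error with estimator error.
Normalization correctness is benchmarked separately against an
independent oracle.  Benchmark problem sizes are 500 features for
recovery/selection, 300 features × 200 resamples for coverage, 300 genes
for the ABC checks, and 1,000 summits for the consensus oracle.

Two statistical limits of the method itself, measured on these
benchmarks, are worth knowing.  First, with 22% per-sample CV, six dosage
levels and seven replicates, the median relative error of the Hill
exponent over good fits sits near 20% (ED50 is much better determined,
median error ≈ 3 percentage points) — the exponent is intrinsically hard
to pin down from this design, which is also why uncertainty is reported
by bootstrap.  Second, equal-complexity AIC selection under multiplicative
noise lets the Hill form absorb apparent curvature in truly linear
features: roughly a quarter of strong linear responders show ΔAIC > 2.
ΔAIC should therefore be read as "Hill describes this feature at least as
well", not as proof of sigmoidality for any single feature.
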