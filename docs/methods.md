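# Methods

This note documents the statistical model behind `ganglimark`, the choices
made where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Normalisation

Two size-factor schemes are computed from the same count matrix, mirroring
the two DE engines' native conventions:

* **median-of-ratios** — `s_j = median_i( y_ij / geomean_i )` over genes
  positive in every sample; used for the exact-test engine and for
  fold-change and VST computation.
* **TMM** — per-sample `2^(weighted trimmed mean of per-gene log2 count
  ratios vs a reference)`, trimming 30 % on M and 5 % on A with inverse
  asymptotic-variance weights, rescaled to geometric mean 1; the reference
  is the sample whose upper quartile of library-scaled counts is closest to
  the mean upper quartile.  M is computed on raw counts, so the factor
  absorbs depth as well as composition and is directly comparable to a
  median-of-ratios factor; used as the GLM engine's offset.

**RPKM** uses `count · 1e9 / (length_bp · library_size)` with the library
size taken as the raw column sum — the simplest reproducible denominator
when the upstream mapped-read total is unavailable.  A gene is *expressed*
in a sample iff RPKM is strictly above 0.3 (strict, following the
threshold's "> 0.3" definition); the union over samples forms the
enrichment background.  (The original expressed-gene definition also used
transcript coverage, which cannot be computed from a count matrix; the
RPKM surrogate is a documented divergence.)

## Dispersion model

Counts are modelled NB with variance `μ + αμ²`.  Per gene, α maximises the
Cox–Reid adjusted profile log-likelihood under the full five-ganglion
one-hot design with log size-factor offsets (the adjustment subtracts half
the log determinant of the expected information of the group means,
reducing the downward bias of plain profile ML).  The search is on
log α ∈ [log 1e-8, log 10]: a 25-point grid brackets the optimum,
golden-section search refines it to 1e-4, and all-zero rows get `NaN`.

The trend `α(μ) = a₀ + a₁/μ` is fitted by least squares of α on 1/μ.
Because the sampling noise of a dispersion estimate scales with the
dispersion itself, the fit is iteratively reweighted by the inverse squared
fitted value (relative-error least squares) with two rounds of outlier
exclusion at 3 robust MADs of the scaled residuals; coefficients are
clamped non-negative.  Plain unweighted LS lets noisy low-mean leverage
points tilt the trend enough to distort downstream type-I error.

Per-gene values are shrunk on the log scale,
`log α* = (d_g log α_raw + d₀ log α_trend)/(d_g + d₀)` with
`d_g = n_samples − n_groups` residual degrees of freedom and prior weight
`d₀ = 10` — enough pooling to stabilise 3-replicate estimates without
erasing genuine gene-level dispersion differences.  One dispersion model is
shared by both engines so that consensus disagreement is attributable to
the test statistics, not to different dispersion estimators (a documented
simplification relative to running each published tool's own estimator).

## The two DE engines

**Conditional exact test.**  Counts are rescaled to a common effective
library (divide by the size factor, multiply by the geometric-mean factor,
round half to even — totals are preserved within ±n/2).  Group sums of n
i.i.d. NB(μ, α) variables are treated as NB(nμ, α/n); at a common success
probability the conditional law of the high-group sum given the total is
negative hypergeometric and free of μ.  The log-pmf over all splits is
computed by a log-ratio recurrence (exact up to cumulative rounding,
~1e-14 for totals ≤ 200) and the two-sided p-value sums every split whose
probability is ≤ the observed one times (1 + 1e-7); p is clamped to (0, 1].
α = 0 is handled as the exact binomial (conditional Poisson) limit.

**NB GLM-LRT.**  Null (intercept) and alternative (intercept + group)
log-link NB GLMs with offsets `log s_j`, fitted by vectorised Fisher
scoring to score norm < 1e-8 (max 100 iterations, steps clipped at ±10 to
tame separation); `D = 2(ℓ₁ − ℓ₀)` clamped at 0 is referred to χ²(1).
Non-converged rows get `p = NaN`, are ignored by BH (m counts non-NaN
p-values only) and can never enter the consensus.

**Consensus.**  `log2fc > 0 AND q_exact ≤ 0.05 AND q_glm ≤ 0.05`
(inclusive), with log2fc computed on median-of-ratios-normalised group
means with a pseudo-count of 0.5.  Exact numerical parity with the two
published tools is *not* claimed; the consensus contract (intersection at
q ≤ 0.05) is what is honoured.

Null calibration: on a no-effect simulation at 2000 genes, each engine's
raw p < 0.05 fraction sits near 0.055–0.068 — slightly above nominal,
driven by the residual downward bias of log-scale dispersion shrinkage,
and inside the accepted [0.03, 0.07] band.

## Marker selection

The dominance filter is read literally: *every* high sample at least
1.5-fold above *every* low sample, i.e. `min(high) ≥ 1.5 · max(low)` on
RPKM, inclusive at the boundary, with ratio +∞ when the low maximum is 0
and the high minimum positive.  (A mean-based reading would admit
overlapping samples.)  The RPKM floor requires every high sample ≥ 10.
A gene passing several groupings is assigned to the one with the smallest
high set — the most specific claim the data support — with ties broken by
larger dominance ratio, then grouping id.  Raising either threshold can
only remove markers (monotone filters), which the tests assert.

## PCA, covariate screen, dendrogram

PCA is an SVD of the gene-centred (unscaled) sample × gene VST matrix,
with a deterministic sign convention (largest-magnitude loading positive).
The VST is the closed form for the fitted trend,
`vst(q) = log2((1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q)))/(4a₀))` with
`q = count/s_j`, strictly monotone with a log2 tail; `a₀ ≤ 0` falls back to
`log2(q + 0.5)` (logged).

The covariate screen reports Pearson r and the exact two-sided t p-value
for every (component, covariate) pair.  Because the scientific claim is
familywise — *no* component correlates with *any* covariate — the screen's
significance flag uses a Bonferroni-adjusted threshold (familywise α =
0.01) across the tested pairs; raw p-values are always reported alongside.
Constant covariates and zero-variance trailing components are flagged
undefined.

Hierarchical clustering is average-linkage agglomeration under
1 − Pearson distance (the standard pairing for multiscale bootstrap
support), implemented directly so tie-breaking is fully deterministic
(lexicographically smallest cluster-key pair); the suite cross-checks it
against an independent linkage implementation.  For node support, genes are
resampled with replacement at scales r ∈ {0.5, …, 1.4} (n′ = round(n·r)),
the tree is rebuilt `nboot` times per scale, and each original node's exact
member set is counted.  Recovery frequencies are clamped to
[1/(2·nboot), 1 − 1/(2·nboot)] and the signed-distance/curvature model
`Φ⁻¹(1 − BP_r) = v√r + c/√r` is fitted by weighted least squares (weights
`nboot·φ(z)²/(BP(1−BP))`) over the *informative* scales — those whose raw
frequency is strictly inside the clamp bounds.  `AU = 1 − Φ(v − c)`,
`BP = 1 − Φ(v + c)`.

Degenerate profiles need care: a constant probit profile is not in the span
of (√r, 1/√r), so a naive fit of a node recovered at the same rate at every
scale returns meaningless v, c and badly distorted AU.  When the profile is
flat or fewer than two scales are informative, the model reduces to
`v = weighted mean probit, c = 0`, so a node recovered at constant rate b
reports AU = BP = b, and a node recovered always reports AU at the clamp
resolution (0.995 at nboot = 100, 0.9995 at 1000).  Never-recovered nodes
report AU = 0 with a flag; nodes clamped at half the scales or more are
flagged `clamped`.

## Enrichment

Exact hypergeometric upper tails, with the EASE variant (tail at k − 1,
p = 1 for k ≤ 1) as the default because it is the behaviour of the
annotation tool the marker panel is conventionally run through; the plain
tail is available by flag.  One row per term with ≥ 1 marker gene, BH over
tested terms, significance strictly below the q threshold (default 0.05).
No term-redundancy removal is attempted.

## Synthetic data generator

The generator emulates the study design at desk scale: 5 ganglia × 3
replicates, 5000 genes, ~1.5 million counts per sample (log-normal
baselines, log-mean log 100, log-sd 1.5; library-size factors log-normal
with log-sd 0.25).  Dispersion follows α(μ) = 0.01 + 2/μ — a typical bulk
trend with ~10 % biological CV at high expression.  Group effects are
independent normal log2 shifts at each node of the known topology
`((Top,Tmm),VA) | (N,P)` with sd 0.2 at the root, halving per level: groups
within a clade co-vary, which aggregated over thousands of genes produces
the observed PCA geometry (modality split on PC1) while keeping individual
null genes far from the 1.5-fold dominance region.  Planted markers (101 by
default, distributed over eight groupings with the visceral and somatic
panels largest) multiply the high-group mean by 2^fc with fc drawn from
[3, 3.5], carry no tree effect, and are planted on genes with baseline ≥ 50
expected counts, since a real marker must clear the RPKM ≥ 10 floor.
Technical covariates (RIN, RNA yield, nominal sequencing depth) are drawn
independently of group — depth from the library-size factor, *not* the
realised column sums, which would leak planted-marker content into the
covariate.  Gene lengths are log-normal (median 2.5 kb).  Annotation terms
are random 40-gene sets; five of them are seeded with planted markers and
constitute the enrichment truth.

What passing recovery tests shows: the pipeline detects 8-fold,
well-expressed markers with 3 replicates at this depth essentially
perfectly, calibrates near-nominally under the null, and reconstructs a
planted two-level topology with high AU.  What it does not show: behaviour
under batch effects, GC/length bias, outlier samples, unbalanced designs,
or markers near the 1.5-fold boundary — none of which the generator
emulates.

## Problem sizes and numerics

Defaults were chosen so a full study runs on a laptop core: 5000 genes × 15
samples, 30 bipartitions × two engines ≈ 30 s, with `nboot = 1000` for
production dendrograms and 100 in the test suite.  The committed toy
fixture (20 genes × 15 samples, two clean markers per modality grouping)
makes every stage hand-checkable.  Numerical guards worth knowing:
dispersion floors at 1e-8; exact-test p-values clamp to (0, 1]; GLM steps
clip at ±10; BH propagates NaN; the VST falls back to shifted log2 when
a₀ ≤ 0; all tabular output rounds to 12 significant digits, which
round-trips losslessly for the quantities reported.
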