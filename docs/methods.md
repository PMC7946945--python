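# Methods

This note documents the models, estimators and design choices behind
`rsikit`, and what the synthetic-data experiments do and do not establish.

## Differential-expression engine

A single moderated-t engine on log2-CPM serves all modalities.  Counts are
filtered (CPM > 1 in at least the smallest group's number of samples, a
conservative default since no standard exists), scaled by TMM factors, and
transformed to log2-CPM with a prior count of 0.5:
`log2((y + 0.5) / (N·f + 1) · 1e6)`.

**TMM.** For each library against a reference (the sample whose
75th-percentile scaled count is closest to the mean), per-gene M-values are
trimmed by 30% at each tail and A-values by 5%; the scaling factor is
2^(weighted mean of surviving M) with inverse-asymptotic-variance weights,
and factors are rescaled to geometric mean 1.  With fewer than 10 genes
surviving the trims the untrimmed weighted mean is used with a warning.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
~1e-10 on a frozen fixture.

**Gene-wise linear models.** Ordinary least squares per gene on a
treatment-coded design (intercept, condition indicators, known batch
covariates).  Nuisance structure is handled as *known* covariates: the
surrogate-variable estimation used upstream in some studies is out of
scope, but the design-matrix code path it would feed is identical.

**Empirical-Bayes hierarchy.** Residual variances follow
s²_g ~ s₀²·χ²_{d₀}/d₀ a priori.  (d₀, s₀²) are fitted by matching the mean
and variance of log s²_g through digamma/trigamma identities, with Newton
inversion of the trigamma function (tolerance 1e-8, ≤ 200 iterations).
If the spread of log s² does not exceed what sampling alone explains, the
prior is degenerate (d₀ = ∞) and s₀² is the arithmetic mean of the sample
variances — the convention of the reference limma implementation, which
this engine matches to ~1e-11 on frozen fixtures (both branches).
Genes with s² = 0 are flagged and excluded from prior estimation.

The DE-coefficient prior variance v₀ is estimated tmixture-style: the top
⌈p₁/2·G⌉ moderated |t| values are equated to their expected tail quantiles
under the alternative; each implied v₀ is clamped to [0.1², 4²]/s₀²
(bounding the prior standard deviation of a true log2 fold change to
[0.1, 4]) before averaging.  The total degrees of freedom d₀ + d_g are
capped at the pooled residual df.

**Posterior probability of DE.** With r = (u + v₀)/u,

B = log(p₁/(1−p₁)) − ½·log r + ((d₀+d_g+1)/2)·log((t̃² + d₀+d_g)/(t̃²/r + d₀+d_g)),

posterior = logistic(B).  The d₀ → ∞ limit uses the quadratic kernel
t̃²(1 − 1/r)/2.  A numerical-integration oracle (marginalizing the variance
prior explicitly) verifies the closed form in the test suite.  p₁ defaults
to 0.01; all prior parameters are recorded in every result, since the
posterior scale (and hence the RSI scale) depends on them.

## Response similarity index

RSI_g = sign(lfc₁·lfc₂)·posterior₁·posterior₂ over the gene-id intersection
of two contrasts.  sign(0) = 0, so a gene with an exactly-zero estimated
fold change gets RSI 0 (measure-zero with continuous estimates, but it must
be defined).  Concordant/discordant genes are counted at |RSI| ≥ τ with
τ = 0.9 by default ("RSI near 1" is threshold-dependent, so counts at
τ ∈ {0.5, 0.8, 0.9, 0.95} are always reported alongside).  Candidate model
systems are ranked against a reference contrast by concordant count, ties
broken by concordant proportion then name.

## Gene-set concordance

Sets are tested by a Wilcoxon rank-sum comparison of member vs non-member
RSI ranks, one-sided in both directions (high = concordant, low =
discordant), sets below 5 surviving members skipped.  The exact null
distribution is used unless both groups exceed 25 observations (full
enumeration of subsets when ties are present and C(n,k) ≤ 2·10⁵), the
tie-corrected normal approximation with continuity correction otherwise.
The concordance curve counts, per candidate, sets with direction `+` and
one-sided p ≤ t over a dense grid of thresholds in (0, 0.05]; the
symmetric discordant curve is also emitted.  Per-sample set scores for
heatmaps are the mean of row-z-scored expression over members — a
deliberately simple visualization-grade summary standing in for the kernel
ECDF-based GSVA statistic, and used nowhere in the concordance inference.

## Cohort similarity

The top n (default 1000) genes of a contrast — ranked by p-value, ties by
|lfc| then name — define the feature space.  Model and patient
log-expression matrices are merged on shared genes and quantile-normalized
(every column mapped onto the mean of order statistics; ties receive the
mean of their target quantiles), row-z-scored, and clustered with average
linkage on Euclidean distances (common heatmap defaults; both
configurable).  Per-gene patient-vs-model contrasts use the two-sided
Mann–Whitney U test: exact when both groups ≤ 8 without ties, otherwise
the continuity- and tie-corrected normal approximation.  Full enumeration
of the 8v8 U distribution shows the worst-case gap between the two branches
is 0.0109, which is the bound the tests assert.

## Drug-response statistics

Luciferase luminescence is calibrated to cell number by an OLS standard
curve (flagged unusable when the slope is non-positive, warned when
R² < 0.9); estimates are floored at zero.  Groups are compared by one-way
ANOVA (identical-values inputs give F = 0, p = 1 flagged; zero within-group
variance with unequal means gives p = 0 flagged) followed by
pooled-variance t tests of each treated group against control, corrected by
the Benjamini–Krieger–Yekutieli two-stage step-up: stage 1 at
q′ = q/(1+q); with 0 < r₁ < m rejections, stage 2 at q′·m/(m−r₁).  The
procedure defines rejections, not q-values, so the reported q-value is the
smallest level at which a hypothesis is rejected, found by bisection
(tolerance 1e-6; the rejection set is monotone in the level).  Group means
carry t-based 95% CIs.  Wells from multiple device runs are pooled as
independent observations by default; a run-blocked analysis can be built
from the per-well table.

## Synthetic-data generator

The generator is the package's definition of the study conditions, not a
tuning knob.  Defaults: 2000 genes; one tumor source; three conditions
(static2D, TMES, xenograft) with n = 6 samples each, the two contrasts
sharing the 2D baseline; per-gene log2 baseline ~ N(5, 2²); NB dispersion
φ log-normal(ln 0.1, 0.5²) with variance μ + φμ² (standard RNA-seq
parameterization); planted |log2 FC| uniform on (1, 3); gene classes 15%
concordant-up, 15% concordant-down, 5% discordant, 5% + 5% single-contrast,
55% null (concordant responses deliberately outnumber discordant ones, the
regime the asymmetry statistic is built for); a gene-wise N(0, 0.5²) batch
offset applied to half the samples of every condition (recorded in the
metadata so the DE design can adjust for it); library-size factors
log-normal(0, 0.3²) so TMM is exercised non-trivially.  Dispersion and
library-size distributions are generic RNA-seq values, configurable, since
no empirical estimates were available to match.

Patient-like cohorts are the xenograft mean log2 profile plus gene-wise
N(0, sd²) heterogeneity.  Drug assays place true cell numbers at
control × effect-fraction and multiply the line intercept + slope·cells by
log-normal noise of a given CV, with a noiseless standard curve.

For model ranking, reference effects are partitioned into co-regulated
expression programs (20 blocks); a candidate model reproduces the effects
of a fixed fraction of whole programs (40% for model A, 10% for model B),
and one gene set is planted per program at purity 0.8 plus random sets.
Program-coherent sharing is the faithful emulation of pathway-level model
similarity: a model system recapitulates whole programs, not independent
random genes — with i.i.d. gene-level sharing, the unshared members of a
planted set scatter into both RSI tails and cancel the shared members, and
the pathway-level curve stops tracking gene-level similarity.

**What passing tests show — and don't.** The generator draws independent
genes (no correlation structure beyond the planted blocks), symmetric
log-normal nuisance, and exactly known batch labels.  Real data have
correlated genes, unknown latent structure, composition effects and
outliers; calibration and recovery results here validate the machinery,
not its behavior under those violations.

## Numerical conventions

Deterministic tie-breaks everywhere: set rankings by p then name; top-gene
selection by p, |lfc|, name; model ranking by count, proportion, name;
clustering follows the linkage algorithm's smallest-index convention.
PCA signs are fixed by making the largest-magnitude loading positive.
All generators are `numpy.random.default_rng`-seeded and reproducible;
the demo pipeline's `summary.json` is byte-identical across reruns of the
same configuration.

## Problem sizes

Simulation-based tests use 800–5000 genes and 50–100 seeded replicates per
claim; these sizes give the binomial/KS assertions comfortable margins
while keeping the whole suite fast, and the acceptance script reports the
`n` it used alongside every value.

## Known limitations

No mean–variance trend in the variance prior (a lowess-trend hook is the
natural extension); no NB GLM or quasi-likelihood engine; no surrogate
variable estimation; quantile normalization is the only cross-cohort
batch adjustment; GSVA proper is not implemented; dose–response modeling
is out of scope (single-dose assays).
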