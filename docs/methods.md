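# Methods

This note documents the statistical procedures implemented in
`econunpred`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic cohort does and does not emulate.

## Ingest and eligibility

A survey response is six binary "hard to pay for" indicators; its score
is their sum (0–6). A response with any missing item is **dropped, not
prorated**: a partial sum would read as lower hardship, and the count of
dropped responses is reported so the choice is auditable. (Whether the
source instrument prorated is unknown; dropping is the conservative
default and the rule is isolated in `score_responses`.)

Responses are bucketed by the **calendar month** of their date — the item
wording ("in the past month") is calendar-anchored — and averaged within
month before the +1 shift to the 1–7 scale. The shift guarantees a
strictly positive mean, which the coefficient of variation requires.
Unobserved months between the first and last observation are retained as
gaps; nothing is imputed at this stage. Eligibility (default: ≥ 15
observed months, the recommended floor for stable unpredictability
statistics on short series) counts observed months, not span length.

## The four unpredictability indices

**Coefficient of variation.** Sample sd (n−1) over mean, computed on the
observed months only. Scale-free; 0 for a constant series.

**Changepoints in mean and variance.** Both kinds minimize a penalized
sum of segment costs. Mean kind: segment cost is the SSE about the
segment mean divided by a global noise variance, estimated robustly as
the squared scaled **median absolute successive difference**
(1.4826·median|Δy|/√2)². Successive differences are immune to the very
level shifts being sought — the plain MAD about the median is inflated
when shifted stretches occupy a large fraction of the series, which
masks detection. Fallbacks for degenerate (heavily quantized or
constant) series: MAD about the median, then the sample variance.
Variance kind: segment cost n_s·(log σ̂²_s + 1) with deviations taken
about the global series mean, minimum segment length 2 (a variance needs
two points); mean kind allows single-point segments.

The search is **PELT** — exact penalized optimization with pruning of
candidate last-changepoints. An exhaustive O(n²) dynamic program
(`segment_optimal`) implements the identical cost, penalty and
tie-breaking and serves as the reference: the two are required to return
bit-identical segmentations, and the pruning inequality keeps a small
tolerance margin so cost ties survive to be broken identically. Ties are
broken toward fewer changepoints, then the earliest boundary, for
determinism. Penalties per changepoint: `mbic` (default) 3·log n,
`bic` 2·log n (one segment parameter plus one location). These are the
penalty *family* of the reference tooling for this analysis, not a
bit-level replication of any package's internals; equivalence is
established against our own exhaustive oracle instead. At the defaults,
a planted mean shift of 4 noise-sd at mid-series (n = 30) is localized
within ±1 position in ≈ 99% of draws while pure white noise yields zero
changepoints in ≈ 93%.

**Noise color.** Spectral estimation needs a regular grid, so this stage
(alone) linearly interpolates internal gaps; a record is flagged when
more than 20% of grid months are interpolated. Systematic structure is
removed by OLS on intercept, linear time trend, and one annual harmonic
pair (sin/cos of 2π·month-of-year/12) — two seasonal parameters, because
series as short as 15 points cannot support eleven month dummies. A
linear trend in spread is then removed by regressing |residual| on time
and dividing by the fitted value, floored at 0.1·median|residual| (or
skipped entirely when residuals are numerically zero). The exponent β is
minus the least-squares slope of log periodogram power on log Fourier
frequency (j/n, j = 1…⌊(n−1)/2⌋), zero-power ordinates excluded, at
least three ordinates required. At n = 1024 the mean absolute estimation
error is ≤ 0.04 across β ∈ {0, 0.5, 1, 2}; at cohort length n = 36 the
estimator is noisy but still separates white from red noise by about two
units of β in the medians.

**Transform.** The reported index is `noise_unpred = −|β̂|` — distance
from white noise, negated so higher = more unpredictable: β = 0 is
maximal randomness, and both red (β → 2) and blue (β < 0) structure are
predictable. The map from β to a published unpredictability score is not
uniquely determined by the verbal description it implements, so the
transform is configurable (`neg` = −β, `shift` = 2−β) and the default is
the unique simple monotone map consistent with randomness peaking at
β = 0 from both sides.

## PCA and the composite

The four indices are z-scored (sample sd) and the correlation matrix
eigendecomposed — correlation-matrix PCA is forced by the stated
standardization. Components are sorted by descending eigenvalue; each is
sign-fixed so its loading on the variance-changepoint count is
non-negative. Scores are the z-data projected on unit-norm eigenvectors
(whether eigenvalue-scaled loadings were used upstream is unknowable;
unit-norm is documented and the composite absorbs the difference only up
to a per-component rescaling — a flagged caveat, not a claim of
invariance). The composite is the weighted average of the k = 2 retained
component scores with weights proportional to their variance-explained
shares; no rotation is applied.

**Caveat:** when the third and fourth eigenvalues are close to the
second, component identity and hence the composite's orientation is
sampling-unstable. In the synthetic cohort the four indices are only
moderately inter-correlated, the leading eigenvalues are close, and the
sign convention is pinned to a feature whose loading is sometimes near
zero — so the composite's correlation with severity varies in magnitude
*and sign* across seeds. Group comparisons in the tests therefore use
individual indices with stable orientation (severity, CV).

## Balancing weights

Confounders are encoded to a fixed 15-column design: education
(6 levels → 5 dummies), income as federal-poverty-level band
(3 → 2), race/ethnicity (6 → 5), child disability (1 dummy), plus child
age and child health continuous. The alphabetical first level of each
categorical is the dropped reference.

**GPS density-ratio weights.** Stabilized inverse-probability weights
for a continuous exposure: the marginal normal density of the exposure
over its conditional normal density given the confounders (OLS mean,
residual variance), normalized to mean 1, optional upper truncation at
the 99th percentile (off by default — the choice is not dictated by the
estimand and trimming trades bias for variance). A near-zero conditional
residual variance is an overlap violation and errors out. These weights
are consistent (the worst weighted exposure–confounder correlation tends
to 0 as n grows) but noisy: at exposure R² = 0.3 the effective sample
size is ≈ 0.55n, so each of the 15 post-weighting correlations carries
≈ 0.06 sampling sd at n = 500, and the *maximum* across confounders
typically sits near 0.11. That imprecision is intrinsic to density-ratio
weighting at this confounding strength — it is the reason
balance-targeting methods exist and win the method selection below.

**Entropy balancing.** Weights minimize Σ w·log w subject to Σw = n,
preservation of every confounder mean and the exposure mean, and exact
zero weighted exposure–confounder cross-moments — which together force
every weighted Pearson correlation to zero exactly. The convex dual
(a log-sum-exp over standardized constraint functions) is solved by
damped Newton with Armijo backtracking; the dual gradient *is* the
vector of weighted constraint violations, and convergence requires its
max below 1e−8 (iteration cap 500). When no positive weights satisfy
the constraints — typical when a dummy has only a handful of positive
cases, so the cross-moment cannot be zeroed without degenerate weights —
the dual diverges or stalls and the solver raises, naming the worst
constraint; this was verified to coincide with genuine LP infeasibility
rather than solver failure.

**Selection.** Per exposure, every requested method runs; a method that
errors is dropped. The winner maximizes the count of confounders with
|weighted r| ≤ 0.10, ties broken by smaller worst |r|, then larger
effective sample size (Kish ESS = (Σw)²/Σw²). On the default cohort's
125-family outcome subsample, entropy balancing wins when feasible and
GPS serves as the fallback in the rare-cell regime.

## Effect models

One weighted least-squares model per exposure — intercept plus exposure,
with the weights doing the confounder adjustment, matching the
weighting philosophy rather than double-adjusting by covariates (a
doubly-adjusted option is a flag). Standard errors are HC3 sandwich
(the exact variance estimator appropriate to estimated weights is not
settled; HC3 is the documented default and a bootstrap is the off-by-
default alternative); confidence intervals are normal-approximation
95%. The standardized slope uses unweighted sample sds of exposure and
outcome. Under planted linear confounding (15 confounders, exposure
R² = 0.3) with a true slope of 0.36: naive OLS is biased upward by
≈ 0.24, while the balanced weighted estimator at n = 125 has mean error
below 0.01, ≈ 96% CI coverage, and a ≈ 3% type-I error rate at nominal
5% under the null.

## The synthetic cohort

The generator emulates the target design: 321 families, a 36-month
window (April 2020 onward), per-family missingness leaving 15–36
observed months (retries enforce the eligibility floor; missingness is
MCAR by default, with an off-by-default MAR option where drop
probability rises with hardship), one response per month by default, and
a 125-family outcome subsample.

Hardship is modeled as **episodes**: a low baseline (log-normal in a
family-level SES-severity latent) punctuated by abrupt stretches of
elevated need — each episode contributes a pair of mean-path
boundaries. Episode frequency scales as exp(0.9·u) in a family
instability latent u; noise level tracks both u and the current hardship
level (families at the zero floor barely fluctuate); planted variance
regimes multiply the spread over random stretches; an annual harmonic
(amplitude 0.3 hardship units, random phase) and 1/f^β colored noise
(deterministic f^(−β/2) amplitudes, uniform random phases; β centered at
0.8 − 0.5·u and clipped to [0, 2]) complete the path, which is rounded,
clipped to 0–6, and +1-shifted — mirroring the bounded sum-score
instrument. Item-level responses are drawn as a uniform random subset of
exactly the planted sum-score size, so ingest reproduces the planted
monthly values exactly with one response per month; a Bernoulli item
model would break that round trip.

The SES latent z drives the sociodemographic confounders (category
sampling utilities shifted by z), the severity latent (ρ = 0.6 with z)
and the instability latent (ρ = 0.5), producing realistic confounding.
The outcome is linear: intercept + 0.36·true severity + 0.21·true
instability + γ′X + Gaussian noise (sd 0.8), with γ concentrated on the
SES-marker dummies. The planted slopes echo the scale of raw effects
reported for comparable severity and unpredictability exposures.
Questionnaire scales (five 1–4 routines items over three
administrations; 18 binary QUIC items with a fixed difficulty spread)
load weakly (0.45) on the instability latent.

Numeric calibration targeted published descriptive conditions for this
kind of cohort — severity mean ≈ 1.6–1.8 and sd ≈ 0.8–1.0 on the 1–7
scale, positively inter-correlated instability indices, a positive
severity–instability latent correlation — and was fixed before any
estimator evaluation.

**What the generator does not emulate.** (1) Real response cadence
(weekly/biweekly phases are reduced to day-jitter within months).
(2) The all-positive leading-component structure reported for real
index data: in the synthetic world the noise index loads *against* the
changepoint counts, because the periodogram-slope estimator reddens on
step-heavy series — episode-prone families look less white even when
their planted noise is whiter. Passing tests therefore demonstrate
pipeline correctness and estimator calibration, not that the synthetic
index geometry matches any particular real cohort. (3) Survey fraud,
stratified recruitment, and measurement non-invariance are out of scope.

**Estimator-calibration scenarios.** `simulate_linear_confounding`
generates the planted linear-confounding design used to calibrate the
weighting estimators: 15 confounders (9 continuous + 6 binaries with
prevalence ≥ 0.15, all sharing one latent), exposure R² = 0.3, outcome
confounding colinear with the exposure-prediction direction so the
naive bias is known in closed form (0.8·R²). This design is full-rank
by construction: near-empty categorical cells make *exact* balance
infeasible outright, which is a property of cell sparsity rather than of
the estimators, and that regime is exercised separately by the cohort
pipeline where method selection falls back gracefully.

## Determinism and problem sizes

All randomness flows from a single root seed through `numpy`'s
`SeedSequence`; identical config + seed reproduces every artifact byte
for byte (CSV floats are written with a fixed format, JSON with sorted
keys). The test suite runs the full 321-family pipeline end to end in a
few seconds; simulation-based checks use 100–500 replicates, sizes
chosen to keep Monte-Carlo error well inside the asserted margins.

## Known limitations

- Changepoint counts on 15–36 points have limited power; shifts smaller
  than ≈ 2.5 noise-sd or shorter than ≈ 3 months are routinely missed.
- β̂ from ≤ 17 periodogram ordinates is noisy and biased red by any
  un-modeled step structure; cohort-scale noise-color values should be
  read comparatively, not absolutely.
- The composite's orientation is unstable when eigenvalues are close
  (see above).
- GPS weights at moderate confounding leave residual random imbalance
  of order 1/√ESS per confounder; entropy balancing removes it exactly
  but can be infeasible in rare-cell designs at small n.
- HC3 intervals ignore weight-estimation uncertainty; empirically they
  are mildly conservative here, but a bootstrap is the safer choice for
  publication-grade intervals.
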