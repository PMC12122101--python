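# Methods

This note documents the models, conventions, and design choices behind
`chumrun`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Cohort reconstruction

Returns are attributed to release-year cohorts through the age ledger: an
age-*a* adult caught in return year *y* was released in year *y − a + 1*.
The reconstruction needs three inputs per region — fry released *X_t*,
return-year totals *y* (coastal catch plus broodstock), and age-composition
surveys. Survey proportions are combined within a return year by
sample-size weighting, p̂ₐ = Σₕ pₐₕnₕ / Σₕnₕ; surveys whose proportions do
not sum to 1 within 1e-6 are rejected with a warning rather than silently
renormalized. Return years with no survey are imputed recursively as the
arithmetic mean of the previous three years' compositions (imputed years
feed later ones), renormalized after averaging to guard floating drift, and
flagged.

The age window is 2–5. Age proportions are **not** renormalized to that
window before allocation: mass at ages 6+ is simply dropped, because such
returns are rare; a `renormalize=True` switch enables the sensitivity
variant. The proportion applied to the year-*y* total is the composition of
return year *y* itself, p̂_{a, t+a−1}.

Return rates are stored as proportions; reporting multiplies by 100.
Additivity R̂_t = Σₐ R̂_{a,t} holds by construction. Merging regions always
pools counts (ΣŶ/ΣX) — a mean of ratios would weight small and large
programs equally. Region summaries report the mean with the 5th/95th
percentile range.

Relative fecundity is eggs per cubic fork length, fecundity/FL³ × 10³
(eggs·cm⁻³·10³); it is computed per fish and then averaged per
(region, year, age), with age-4 and age-5 kept separate. Fry
size-at-release is the release-count-weighted mean of event body weights.

## Regional clustering

Distances between regional return-rate series are 1 − r with r the Pearson
correlation on the untransformed rates over the pairwise-complete year
intersection (at least 3 common years per pair; a zero-variance series is an
error naming the region). The tree is classic neighbor joining: join the
pair minimizing Q(i,j) = (m−2)d(i,j) − Σd(i,·) − Σd(j,·), standard
three-point limb lengths, matrix reduction by
d(new,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties in Q break lexicographically by
label; negative branch lengths are clamped to zero with a log note. The
implementation is checked against scikit-bio's NJ and against additive
matrices, where it must reproduce all leaf-to-leaf distances exactly. How a
merge mapping is read off the tree is a judgment call; the mapping is
therefore configuration, with the seven-to-four pooling shipped as the
default (`cohort.DEFAULT_REGION_MERGE`).

## Covariates

High-seas SST covariates are box means over four named lat/lon rectangles
(southern Sea of Okhotsk, western North Pacific, central Bering Sea, central
Gulf of Alaska) with month windows (July; Jan–Apr; Aug–Sep; Jan–Apr). Cells
enter by center-in-box with inclusive bounds — the field convention for
`fldmean`-style extraction — weighted by cos(latitude); missing cells leave
both numerator and denominator. Longitudes are normalized to 0–360
internally, so either grid convention gives identical means. Coastal
release-window SSTs average member areas first, then the region's release
months (Feb–Jun windows by region); the order matters only for unbalanced
data and is fixed and documented.

Each covariate carries a lag relative to release year *t* (e.g. a
competitor index at *t* + 2); rows with any missing lagged value are dropped
listwise with a logged list. Standardization is (x − mean)/sd with the n−1
denominator, recording the constants for back-transformation. Standardized
and raw fits have identical fitted values, R², and AICc (affine invariance),
so standardization affects only the coefficient scale used for
cross-covariate comparison; practical effect sizes use raw units
(°C, 100 tons, 10⁷/10⁸ fish, 0.1 g, 10² eggs).

## Predator screen

The species × year catch matrix is decomposed by PCA with years as
observations. The default is correlation PCA (centered and scaled) because
catches span orders of magnitude; covariance PCA is available. The sign
convention makes each component's largest-magnitude loading positive;
zero-variance species are excluded with a warning.

The second screening stage is operationalized as a breakpoint rule: a
species is a candidate when (a) it loads positively on the temporal-change
component and (b) its post-breakpoint (default 1998) mean catch exceeds the
pre-breakpoint mean by a configurable ratio (default 1.5) with a positive
post-breakpoint linear trend; candidates are ranked by the ratio. Under
correlation PCA there is no "catch level" component, so by default the
screen selects the component whose year scores correlate most with time,
oriented so the correlation is positive; species driving a recent increase
then load positively. An explicit component override is available.

## Regression pipeline

The response is the natural log of the cohort return rate (a proportion;
using percentages would only shift the intercept). OLS is solved by least
squares with SEs from σ̂²(ZᵀZ)⁻¹, σ̂² = RSS/(n−p). The intercept is always
included and never a selection candidate.

**AICc convention.** k counts the coefficients including the intercept plus
the residual variance (Gaussian likelihood convention): with p coefficients,
k = p + 1 and AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1). Other conventions
shift all models by a constant and cannot change rankings. RSS is floored
at 1e-300 before the log so perfect fits rank first with finite AICc.

**VIF screening.** VIFⱼ = 1/(1−R²ⱼ) from regressing column j on the others
with intercept; the largest is removed (ties break lexicographically;
perfect collinearity counts as infinite) until all are below 3.0.

**Selection.** All 2^s subsets of the retained covariates are fitted
(subsets too large for n are skipped with a warning; enumeration is guarded
at s ≤ 20). Ranking ties break toward fewer covariates, then name order.
Every non-empty combination of the three covariate groups is evaluated with
its own VIF screen; the winning combination has the minimal min-AICc, ties
resolving toward fewer groups, then fewer covariates.

**Averaging.** Akaike weights ∝ exp(−AICc/2) over models within ΔAICc < 2
of the best. Averaging is conditional — a term is averaged over the models
containing it, and its summed weight is reported alongside — which is the
natural reading of averaging "the regression coefficients"; full
(zero-substituted) averaging is available via a flag.

**Effect sizes and prediction.** Effects are exp(β̂) per practical unit with
CI exp(β̂ ± 1.96·SE) and percent change (exp(β̂)−1)×100. Predictions are
made on the log scale and back-transformed; 95% prediction intervals use the
t quantile with the 1 + x₀ᵀ(XᵀX)⁻¹x₀ leverage term. Rows more than 3 SD
from the training covariates trigger an extrapolation warning, not an error.
The predicted-observed Pearson r is reported with its t statistic.

**Diagnostics.** Externally studentized residuals (leave-one-out variance)
are compared to a pointwise 95% QQ envelope built from 1000 seeded
standard-normal samples of the same n; the fraction of points inside is
reported. Perfect fits skip diagnostics with a notice.

## Year-trend smoother

A penalized cubic regression spline approximates the GAM-style year trend:
B-spline basis (default dimension 10, capped at n−2; knots at evenly spaced
quantiles of year), exact second-derivative penalty (Gauss–Legendre on each
inter-knot interval), and λ chosen by GCV = n·RSS/(n − γ·tr(H))² over a
log-spaced grid, with γ = 1.4 mildly inflating the effective df to curb the
known tendency of GCV to undersmooth short series. The penalty's null space
(constant + linear) is kept exactly unshrunk, so λ → ∞ recovers the
straight-line fit and an explicit basis_dim = n with λ → 0 interpolates.
Computations use the Demmler–Reinsch parameterization, making the edf and
RSS profiles O(basis dimension) per λ.

Trend significance uses the approximate F statistic of the smooth against
the intercept-only model on the effective df. Its classical F reference is
anticonservative for GCV-selected smooths (the smoothing parameter adapts to
the data), so the default reference is Monte Carlo: the statistic is
location/scale-invariant under the Gaussian no-trend null, and 199
standard-normal series of the same length — each re-smoothed with its own
GCV-selected λ — calibrate the test including the selection adaptivity. The
classical reference remains available as `reference="f"`. Only the combined
smooth-vs-null test is offered; no decomposition into separate linear and
nonlinear year effects is attempted.

## Synthetic generator

The generator mirrors the fitted model so that recovery is a meaningful
check: per region and release year, R_t = exp(β₀ + Σβᵢz_{i,t} + ε_t) with
ε ~ N(0, noise_sd²) and independent AR(1) (ρ = 0.3) covariates standardized
per region. Defaults encode the study conditions: release years 1998–2019
(22 cohorts), ages 2–5 with schedule (0.05, 0.55, 0.35, 0.05) reflecting
age-4 dominance, ~1.5×10⁸ fry released per region-year (lognormally
jittered), baseline survival exp(β₀) = 2%, noise SD 0.3, and coefficients
of magnitude 0.3–0.45 for the three active stressors. Rates implying
R_t > 1 raise an error naming the year.

Cohort returns are round(X_t·R_t), split across ages by largest-remainder
integerization so cohort totals are conserved exactly — conservation is a
test invariant, not an approximation. Age surveys are multinomial draws of
`survey_sample_n` fish per return year; `exhaustive_surveys=True` writes
the exact composition with the full return count, which together with
noise_sd = 0 makes end-to-end reconstruction exact up to the half-count
rounding bound (≤ 0.5/Ŷ_t on the log scale). All randomness derives from
one integer seed through fixed per-stage sub-seeds, so each stage is
independently reproducible.

The SST grid is month climatology (seasonal cosine peaking in August, a
linear latitude gradient) + linear year trend + iid noise with a persistent
random land mask. The catch matrix is lognormal AR(1) per species with one
species ramping on the log scale after a breakpoint year. The generator
does not attempt realistic spatial covariance of SST, fishery selectivity,
mixed-stock straying between regions, or freshwater mortality — passing
tests show the estimators are correct under the stated model, not that the
model captures every feature of real monitoring data.

## Problem sizes and runtimes

Test and acceptance computations use the study-scale sizes: n = 22 release
years per region, 4 regions, 8-candidate selection problems (2⁸ subsets),
200 replicates for selection recovery, 500 for CI coverage, 1000 null
replicates for trend-test calibration (with 199 Monte Carlo null draws per
test), and 10–20 random matrices for the NJ checks. These sizes give
binomial Monte Carlo error comfortably inside the asserted bands.

## Known limitations

* The trend module approximates, not replicates, reference GAM machinery
  (basis, penalty, and selection criterion differ in detail); its
  deliverable is the fitted curve and trend verdict.
* Model-averaged coefficients are conditional averages; selection-conditional
  bias of post-selection estimates is a known phenomenon and is not
  corrected, only measured on synthetic truth.
* No interactions, no beta-regression (logit-link) variant, no mixed-effects
  or state-space alternatives; observational associations only.
* The published regional coefficient tables and PCA variance shares depend
  on the archived real dataset and are not reproducible from synthetic
  inputs; the package verifies the arithmetic and the method's operating
  characteristics instead.
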