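# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is tested against — including what those tests do and do
not establish about real survey data.

## Growth-model fitting and selection

Each site's series is a vector of yearly abundances; for party-hour
surveys the counts are first divided by effort, so the fitted quantity is
birds per party-hour. Time is measured from the site's first observation
year, so the exponential intercept N₀ is the abundance at first
detection and "population age" is the observed span.

All three families — exponential, quadratic, logistic — are fitted with
additive Gaussian errors on the (effort-normalized) count scale, with the
residual standard deviation profiled at its maximum-likelihood value.
One scale for every family is what makes the log-likelihoods, and hence
the AICc scores, comparable across families; a log-scale exponential fit
and a count-scale logistic fit would not be. The reported growth rate,
however, is the classical log-linear OLS slope (see below), not the
nonlinear count-scale estimate. Parameter counts for AICc include sigma:
3 (exponential), 4 (quadratic), 4 (logistic). AICc is undefined for
n ≤ k+1 and reported as +inf.

Numerical details:

- Exponential and logistic curves are fitted with bounded trust-region
  least squares and analytic Jacobians. The exponential rate is
  unconstrained in sign; a negative best-fit rate is how monotone decline
  is detected. The quadratic is an exact polynomial LS fit.
- Logistic parameterization N(t) = K/(1+e^(−r(t−t_mid))), with
  K ∈ [0.5·max(N), 100·max(N)], r ∈ [−5, 5], t_mid ∈ [t₀−50, t_end+50].
  The sign range of r admits the decreasing ("negative logistic")
  pathway. Starting values form a 3×3 grid over K (1.05, 2, 5 × max) and
  t_mid (quartiles of the window), with the initial rate sign taken from
  the linear trend; the grid points are ranked by their starting SSE and
  the optimizer is run from the best three, stopping early on an
  essentially exact fit.
- A logistic fit is declared non-convergent (AICc +inf) when the
  optimizer fails, when a parameter is pinned at a bound, or when the
  fitted inflection lies outside the observed window (t_mid beyond the
  last observation for growing fits, before the first for declining
  ones). The last rule is an identifiability condition: a series that
  never passes its inflection shows pure accelerating growth, and the
  asymptote would be extrapolation rather than estimation. This mirrors
  the maximum-likelihood non-convergence seen in practice when a logistic
  is a poor empirical description of a series.
- Residual variance is floored at 1e−12 so that exact fits give large
  finite log-likelihoods instead of infinities; exact AICc ties are then
  broken toward the family with fewer parameters, and after that by a
  fixed order (exponential, logistic, quadratic).

**Classification.** The lowest-AICc converged family labels the site.
If that best fit is monotone non-increasing over the observed window —
negative exponential rate, a quadratic whose derivative 2at+b is ≤ 0 at
both window endpoints, or a negative-rate logistic — the site is labeled
`decreasing` and excluded: since the species was absent everywhere
initially, a declining best fit means the series began after the local
rise was over. Sites with fewer than 8 observed years are excluded
first; sites with no converged fit are `unresolved`. Each site carries
exactly one label and at most one exclusion reason.

**Carrying capacity.** Quadratic label (a < 0): K = c − b²/4a, the value
where the fitted derivative is zero, an upper limit on local carrying
capacity; a vertex time outside the window is flagged but kept.
Logistic label: K is the asymptote parameter. An exponential-labeled
site still contributes a K when a quadratic or logistic alternative has
ΔAICc < 2, taken from whichever of the two is better supported.

**Growth rate.** Wherever the exponential family's ΔAICc < 2 (strictly),
r is the OLS slope of log abundance on calendar year. Leading zeros
(years before first positive count) are dropped; if interior zeros
remain, a 0.5 offset is added inside the log — otherwise the plain log
is used, so noiseless exponential data return the exact rate. At least 3
usable points are required.

## Predictors and standardization

Eleven predictors: invasion distance (haversine great-circle distance,
Earth radius 6371.0088 km, from the introduction origin — deliberately
ignoring land/water barriers), population age (first to last observed
year; the last year of each series is the reference, since the analysis
end date is survey-specific), four developed-cover percentages, forest,
pasture and crop percentages, mean annual precipitation and temperature.

Both predictors and responses are centered and scaled to sample
(n−1) standard deviation 1. `independent` mode standardizes within each
dataset tag (route-survey-like vs count-circle-like); `joint` mode pools
the tags first, preserving between-survey mean differences as nonzero
within-tag means. Constant columns are centered, flagged, and not
scaled. The fitted means/sds are retained so predictions can be mapped
back to the original response scale exactly.

## All-subsets model averaging

All 2^p main-effects OLS subsets (p = 11 → 2048 models, including the
intercept-only model; enumeration is refused for p > 20) are fitted via
shared Gram matrices — for subset s, β solves (D'D)[s,s]β = (D'y)[s] —
which is algebraically ordinary OLS but fast enough to sit inside
cross-validation folds and replicate studies. Rank-deficient subsets are
flagged and excluded from weighting. Each model gets a Gaussian
log-likelihood with profiled sigma, R², AICc, and an Akaike weight.

Averaged coefficients come in two modes. `conditional` (default)
averages each variable over the models that contain it with weights
renormalized to that subset — the natural reading of averaging "across
the models in which the variable occurs". `full` substitutes zero where
the variable is absent without renormalizing, shrinking weakly supported
coefficients toward zero. Importance w_i₊ is the summed weight of the
containing models in both modes; the intercept is averaged over all
models. The "model-averaged R²" is defined here as the R² of the
predictions made with the averaged coefficient vector — an
interpretation, since model-averaged fit has no unique definition.
No pre-averaging candidate-set reduction is applied.

Gridded prediction covers the site bounding box at 0.5° cells;
covariates at cell centers are inverse-distance-weighted means of the 5
nearest sites (synthetic covariates exist only at sites, not as
rasters), standardized with the training parameters, predicted with the
averaged coefficients, and back-transformed; negative abundances are
floored at zero and flagged.

## Validation

**LOOCV.** Each of n folds refits on n−1 sites and predicts the held-out
site. The default refits the single full 11-predictor OLS (the model
whose coefficients the averaging weights); a `reaverage` mode reruns the
entire 2048-model averaging inside every fold. PRESS is the summed
squared held-out error; R²_cv = 1 − PRESS/SST with SST about the
full-sample mean (one of several possible conventions; recorded here
because the alternative — a squared correlation — differs). Shrinkage is
100·(R²_fit − R²_cv)/R²_fit. The fold loop is checked in tests against
the closed-form leverage identity e_i/(1−h_ii).

**Moran's I.** For each great-circle distance band with binary weights,
I = (n/W)·Σ w_ij z_i z_j / Σ z_i², expectation −1/(n−1) under no
autocorrelation. Default bins: 10 equal-width bands to the 90th
percentile of pairwise distances plus one catch-all band to the maximum,
so every pair is counted. A two-sided permutation envelope (default 199
seeded relabelings, 95%) marks the no-structure reference. Constant
inputs are rejected; empty bands are skipped with a note.

## Synthetic invasion generator

The generator emulates the sampling structure of continental bird-survey
data during a range expansion, with defaults chosen as one plausible
quarter-century invasion (1986–2010, southeastern origin, 300 sites over
the conterminous-US bounding box):

- **Colonization**: arrival = distance/velocity + N(0, 0.7) years,
  velocity 150 km/yr (the scale needed to cross the continent within the
  simulated period); with probability 0.03 a site is instead colonized
  early by a jump, advancing its arrival by Exp(800 km)/velocity years.
  Arrival is clipped to the simulated period, so the far tail is
  censored at the end year.
- **Observation**: series start after a geometric detection lag
  (mean 1 year) and run to the end year. Effort (party-hours) is drawn
  log-uniformly in [4, 60] per site-year and multiplies the expected
  count before noise; default noise is median-unbiased lognormal
  (σ = 0.2); Poisson and noise-free modes exist.
- **Covariates**: seven land-cover percentages and two climate variables
  are Gaussian random fields with exp(−d/500 km) covariance, realized by
  dense Cholesky (jitter fallback if numerically non-PD), mapped to
  natural scales and clipped to valid ranges.
- **Truth**: true K = 60 + 9·z(developed-medium) − 6·z(developed-high)
  − 7·z(precipitation) + N(0, 5), floored at 5; true
  r = 0.35 + 0.09·z(distance) − 0.06·z(forest) + N(0, 0.04), floored at
  0.05. Linear links on standardized covariates match the linear
  main-effects analysis downstream.
- **Families**: the configured mix (0.35 exponential, 0.35 logistic,
  0.20 hump, 0.10 decreasing) is honored exactly up to rounding;
  decreasing sites are scattered at random (detection failures can occur
  anywhere), and the rest are assigned by population-age rank — oldest
  sites hump-shaped, intermediate logistic, youngest exponential. This
  is the phenomenological reading of observed-window truncation: every
  site may follow saturating dynamics, but young sites are seen only in
  their accelerating phase. It is what gives the simulated invasion its
  model-type geography (exponential labels far from the origin,
  hump-shaped labels in the old core). The hump family is a concave
  quadratic floored at zero — deliberately phenomenological; the
  generator does not arbitrate between overshoot and traveling-wave
  explanations of observed declines.
- **Reproducibility**: one root seed; coordinates, colonization timing,
  jumps, lags, effort, and count noise come from per-site streams keyed
  by a stable hash of the site id, so adding sites leaves existing
  sites' placement and noise untouched. The covariate field is the one
  jointly realized quantity (a random field over all site locations), so
  covariate values — and through them the true K and r — do depend on
  the full site set. Identical configurations give byte-identical CSV
  exports.

**What passing tests show — and don't.** Recovery and sign-consistency
results on this generator demonstrate that the estimation chain is
correct when the data-generating process matches the fitted families,
noise is well-behaved, covariate links are linear, and detection is only
briefly lagged. Real survey data violate all of these to unknown
degrees: observer turnover, zero-inflation, range-wide trends, nonlinear
habitat responses, and spatially structured residual processes are not
emulated. Synthetic results validate the software and the statistical
identities, not the ecological conclusions one would draw from any
particular survey.

## Problem sizes and runtime choices

Default study sizes keep a full analysis interactive: 300–400 sites per
simulated invasion, 2048-model enumerations, 199-permutation envelopes,
and replicate studies of 50 runs for sign-recovery and 100–200
replicates for selection/recovery rates. The acceptance script uses the
same sizes except for a 5-run sign-recovery study, which is sufficient
for a pass-rate summary at its reporting precision.

## Known limitations

- Gaussian count-scale errors are a pragmatic compromise; a count
  likelihood (negative binomial) would weight low-abundance years
  differently.
- Conditional averaging overstates coefficients of rarely included
  variables; the full-averaging mode is provided, and importance weights
  should be read alongside either.
- The grid prediction inherits the site-interpolation of covariates;
  with real rasters the interpolation step should be replaced by zonal
  extraction.
- LOOCV is not spatially blocked; with strong residual autocorrelation
  it overstates predictive skill — which is exactly what the Moran's I
  residual correlograms are there to check.
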