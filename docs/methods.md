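# Methods

`heatlag` implements a two-stage time-series analysis of how the short-term
association between summer heat and daily mortality changes *within* the
summer, together with a synthetic-data generator that makes every stage
testable without access to restricted mortality registries.

## First stage: location-level time-varying DLNM

For each location, daily death counts `Y_t` over a 4-month summer window are
modelled with a quasi-Poisson log-linear regression,

    log E[Y_t] = alpha + cb_t' theta + (d_t - d0) cb_t' gamma + confounders,

where `cb_t` is the 12-column DLNM cross-basis

    cb_t[(j,k)] = sum_{l=0..10} R_j(x_{t-l}) C_k(l),

with `R` a quadratic B-spline in temperature (3 df; one interior knot at the
location's 75th summer-temperature percentile, boundary knots at the summer
min/max, first column of the full basis dropped) and `C` a natural cubic
spline in lag (4 df; explicit intercept column plus interior knots at
10^(1/3) and 10^(2/3), i.e. equally spaced on the log-lag scale, boundary
[0, 10]).  Lags are evaluated at the 11 integer days 0..10, and lag windows
never cross between summers: ten burn-in temperature days precede each
summer so every analysed day has a complete window (without burn-in data the
first ten days of each summer are dropped from the likelihood).

The interaction block multiplies the cross-basis columns by day of season
centred at `d0`, so `theta` is the surface on day `d0` and `gamma` its
per-day linear change.  Centring is a reparameterisation only: the column
space, fitted values and likelihood are invariant, and the surface on any
day `d` is

    theta(d) = theta + (d - d0) gamma,
    V(d)     = V_tt + (d - d0)^2 V_gg + (d - d0)(V_tg + V_tg').

Early and late summer are the midpoints of the first and last summer months:
days 15 and 107 of the default 122-day window (both configurable).

Confounders: a natural cubic spline of day of season (4 df, interior knots
equally spaced over the window) interacted with per-summer indicators; a
natural cubic spline of calendar time with roughly 1 df per decade (floor
1); six day-of-week indicators; optionally a 3-df natural cubic spline of
the lag 0-1 mean of relative humidity and a linear term in diurnal
temperature range.  Fitting uses IRLS (statsmodels GLM, deviance change
< 1e-9, at most 100 iterations); the dispersion is the Pearson estimator
`phi = X2/(n-p)` and the coefficient covariance `phi (X'WX)^{-1}`.  A
dispersion outside [0.5, 10] raises a warning.

## Reduction

The 12 surface coefficients are collapsed to two one-dimensional summaries
by exact linear maps (covariance `M V M'`):

* overall cumulative exposure-response: `u_k = sum_l C_k(l)` gives a 3x12
  map onto exposure-basis coefficients of the lag-cumulated curve;
* lag-response at `x*`: `r_j = R_j(x*) - R_j(x_ref)` gives a 4x12 map onto
  lag-basis coefficients of the curve `s(x*, l) - s(x_ref, l)`.

Because the exposure basis omits the constant, only curve *contrasts* are
identified; overall-cumulative sets therefore carry a reference temperature
and are always displayed as `f(x) - f(x_ref)`.

Reduction is two-pass.  Pass 1 reduces overall-cumulative sets with the
location median temperature as a provisional reference (the reference does
not enter the reduced coefficients, only their display) so that pooling can
proceed.  After the second stage, location-specific minimum-mortality
percentiles are derived from BLUP curves, and pass 2 re-reduces the lag sets
with `x* =` the location 99th percentile and `x_ref =` the location BLUP
MMP temperature.  The provisional reference is recorded in the outputs.

## Second stage: REML multivariate meta-regression

Reduced sets `y_i` (k = 3 or 4) with within-location covariances `S_i` are
pooled across locations under

    y_i ~ N(X_i b, S_i + Psi),

with meta-covariates: country indicators (no global intercept) plus the
location's summer temperature mean and range, centred at their grand means.
`Psi` (unstructured, k x k) is estimated by REML on its Cholesky factor
(start `sqrt(0.1) I`) with the analytic gradient and BFGS (gradient
tolerance 1e-9; a short Nelder-Mead polish runs if the line search stalls
near the `Psi = 0` boundary, which is a stationary point of the Cholesky
parameterisation).  Fixed effects are GLS at the REML solution.  Country
predictions set the country indicator and the climate covariates to the
country averages; BLUPs shrink each location's estimate toward its
meta-regression prediction by `Psi (S_i + Psi)^{-1}`.

The within-summer change is tested per country with a multivariate Wald
statistic `W = b' V^{-1} b` on the pooled reduced *interaction* sets (k = 3,
chi-square df 3); the null is a constant exposure-response throughout the
summer.  A singular `V` falls back to the pseudo-inverse with rank-adjusted
df and a warning.

## Reported summaries

Curves are reported on a relative percentile scale.  Location tables are
type-7 empirical percentiles (0..100) of the analysed summer temperatures;
a country table is the percentile-wise average of its location tables, and
the country-level exposure basis is rebuilt from that table (knots at the
country-average percentile values).  The minimum-mortality percentile (MMP)
is the argmin over percentiles 1-99 (step 1, ties toward the lower
percentile) of the no-interaction overall cumulative curve.  Relative risks
at the 90th/99th percentiles versus the MMP carry Wald-type 95% intervals,
symmetric on the log scale.  Lag curves are evaluated on a 0..10 grid in
steps of 0.25 for display and at integer lags for consistency checks (their
integer-lag sum equals the overall cumulative value at `x*`).

## Synthetic world

The generator is the model class the pipeline fits, so estimates are
consistent and recovery is a meaningful test.

* Weather: `x_t = m + A sin(pi (d - 0.5)/D) + e_t`, with AR(1) noise
  (`rho = 0.6`, innovation SD 2.5 C, stationary start); defaults `m = 22 C`
  (per-location spread SD 1.5 C so the climate meta-predictors have
  support), `A = 4 C`, `D = 122` days (a June-September analogue), 10
  burn-in days per summer.
* True surface: separable per anchor day.  The exposure-response is a
  quadratic in temperature with vertex at the minimum-mortality percentile
  (default 60th for both anchors) scaled to `logrr99` at the 99th
  percentile of the *analytic* marginal temperature distribution (mixture of
  normals over the summer days, inverted on a fine grid); the lag
  distribution is a normalised discretised exponential `w(l) ~ exp(-delta
  l)` on lags 0..10.  The day-`d` surface linearly interpolates the early
  (day 15) and late (day 107) anchor surfaces -- exactly the linear
  interaction form -- extrapolating linearly outside the anchors.  Defaults:
  `logrr99` 0.35 (early) and 0.05 (late), decay 0.3 (early) and 1.0 (late).
  The quadratic is taken on the temperature scale so that the exposure
  contrast lies exactly in the fitted spline span; the pure percentile-scale
  oracle `true_cumulative_logrr` agrees with it at the anchor points (the
  MMT, where the value is 0, and the 99th percentile).  With distinct early
  and late MMT percentiles the value at the *interpolated* MMT percentile is
  only approximately zero; the default world keeps them equal so the oracle
  is exact.
* Counts: `mu_t = baseline * exp(seasonal + dow + heat)`, with a mild
  seasonal log-cycle (amplitude 0.05) and day-of-week log-cycle (amplitude
  0.02), baseline 20 deaths/day.  Overdispersion `phi = 1.2` uses a negative
  binomial with `Var = phi mu` (matching the two moments quasi-Poisson
  relies on); `phi = 1` is exact Poisson.
* Heterogeneity: per-location `logrr99_early/late` are independent normal
  draws around the surface values (SD 0.05), so locations differ in both
  curve scale and (implicitly) interaction slope.

What the generator does **not** emulate: influenza and air-pollution
confounding, population drift, reporting artefacts, missing data (beyond
the reader's optional gap imputation), spatially correlated weather, or
asymmetric cold effects.  A green recovery test therefore establishes
internal consistency of the estimator under its own model class, not
robustness to real-data violations.

## Numerical choices and degenerate inputs

* Spline evaluation uses `scipy.interpolate.BSpline` (Cox-de Boor); the
  natural-cubic constraint is the QR projection of the boundary
  second-derivative rows.  Points beyond the boundary knots are evaluated by
  linear extrapolation (the natural-spline convention, applied to both
  families) and flagged.
* Quantiles are type-7 (linear interpolation of order statistics)
  throughout.
* Tied percentile knots, rank-deficient designs (reported with the
  offending block), negative or non-integer counts, series shorter than the
  lag window, and overflowing simulated rates are rejected with messages.
* `x* = x_ref` in the lag reduction yields the all-zero set rather than an
  error.
* Locations failing the first stage are excluded with a logged reason; the
  pipeline aborts if more than 20% fail.  Missing days in read data are
  rejected unless at most 5% per summer and imputation is requested (linear
  temperature interpolation; flagged).

## Known limitations

* Early-summer estimates extrapolate the interaction to a day with few hot
  observations; their per-location sampling SD (~0.35 in log-RR at the 99th
  percentile in the default world) dominates the pooled uncertainty, and the
  pooled early estimate carries a small (~2-4%) finite-sample attenuation
  that vanishes as the per-location information grows.
* The exponential-decay lag truth is strictly positive at every lag, so
  zero-crossing summaries of estimated lag curves behave noisily where the
  curve hovers near zero (late summer, long lags).
* The Wald test treats `Psi` as known; with few locations it is mildly
  conservative (null p-values stochastically larger than uniform), and
  markedly so when the true `Psi` is exactly zero, since the REML estimate
  sits on the boundary and `Psi-hat >= 0` inflates the pooled covariance.
* GLS pooling with estimated `S_i` induces the usual slight small-sample
  attenuation of inverse-variance weighting.
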