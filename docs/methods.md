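# Methods

`countercast` implements Bayesian posterior-predictive counterfactual
evaluation of an intervention's effect on a focal time series: fit a
regression model to the pre-intervention data only, forecast the
post-intervention window from the posterior-predictive distribution, and
express the intervention's apparent effect as the ratio of observed to
forecast outcomes and the probability that the observed value exceeds the
forecast.  The approach is conceptually aligned with synthetic-control
methods: the counterfactual is carried by reference series (or, for a
single seasonal series, by its own seasonal-trend structure) that were not
affected by the intervention.

## Model families

All three families share the same weakly informative prior scheme:
Normal(0, 10) on the intercept, Normal(0, 2) on every other regression
coefficient, and half-Student-t(df 3) priors on positive dispersion
parameters — scale 25 for the beta precision and the NB2 dispersion, scale
2 for the log-normal residual SD and the spline wiggliness SD.

**Beta regression (relative search frequencies).**
`y_i ~ Beta(mu_i, phi)` in the mean–precision parameterization (shapes
`p = mu*phi`, `q = (1-mu)*phi`, so `mu` is the mean and `phi` the
precision), with `logit(mu_i) = X_i beta`.  The design holds the reference
series' main effects plus all pairwise products ("first-order
interactions"): with k references, `1 + k + k(k-1)/2` columns.  Because the
beta likelihood has no mass at 0 or 1, the single period at the series
maximum (exactly 1.0 after relative rescaling) is replaced by 0.99 before
fitting.  Exact zeros — which the source data description leaves
unaddressed — are replaced by `(1-0.99)/2 = 0.005` with a warning; this is
this package's own convention, chosen symmetric to the documented maximum
substitution.

**NB2 regression (import counts).**
`y_i ~ NB2(mu_i, phi)` with `log(mu_i) = X_i beta` and variance
`mu + mu^2/phi` (smaller `phi` = more overdispersion).  The design is
main-effects only: raw reference counts, untransformed, matching the
convention that priors are interpreted on the raw predictor scale.
Reference series whose fraction of exact zeros exceeds 50% carry almost no
counterfactual signal and destabilize the log-link fit; they are dropped
and logged.  The 50% threshold is this package's default (the qualitative
rule "overwhelmingly dominated by zeros" fixes no number).

**Seasonal log-normal additive model (visitation).**
`log(y_i) ~ Normal(mu_i, sigma^2)` with
`mu_i = M_i beta_1 + s(T_i)`, where `y` is in units of 100,000 visits,
`M_i` is a January-base month factor (11 dummy coefficients with the slope
prior), and `s` is a penalized smooth over decimal time standardized by the
pre-period mean and twice the pre-period SD (so pre-period standardized
time has SD 0.5 and the slope priors are on a sensible scale).
Standardization constants are frozen from the fitting period: forecast
months are transformed with pre-period center/scale, never their own.

## The spline smoother

The smooth is a cubic B-spline basis (10 basis functions by default, equally
spaced clamped knots spanning the fitting range) with a second-order
difference penalty, re-parameterized in mixed-model form the way mgcv-style
smoothers are: the penalty null space — constant and linear — is split off
as unpenalized fixed effects (the constant is absorbed by the intercept;
the linear trend becomes a design column carrying the ordinary Normal(0, 2)
slope prior), and the remaining 8 columns are random effects with
exchangeable Normal(0, spline_sd) coefficients.  The single `spline_sd`
hyperparameter (half-Student-t(3, 2) prior) therefore controls exactly the
wiggliness of the smooth, not its level or slope.  An earlier design that
ridge-penalized the raw B-spline coefficients was discarded because it
shrinks the smooth's boundary level toward the series mean, producing a
visible over-prediction bias in the forecast window; the null-space split
removes that mechanism.

Forecast times beyond the last fitting knot use linear extension: each
basis column is continued from its boundary value with its boundary slope,
so the smooth extrapolates as a straight line rather than oscillating.
This is a deliberate design choice for forecasting with penalized splines,
which the underlying model leaves open.

## Posterior computation

Sampling uses Hamiltonian Monte Carlo written for this package (numpy/scipy
only) with analytic gradients of every likelihood and prior:

* positive parameters (`phi`, `sigma`, `spline_sd`) are sampled on the log
  scale with the Jacobian included;
* the spline random effects use a non-centred parameterization
  (`coefficients = spline_sd * z`, `z ~ N(0,1)`) to remove the funnel
  between coefficients and their SD;
* design columns are internally rescaled by their SD so coefficients of
  raw-count predictors (magnitudes of hundreds) and unit-interval
  predictors sample on comparable scales — invisible outside the sampler;
* warm-up adapts the step size by dual averaging (target acceptance 0.8)
  and estimates a dense mass matrix from two successive draw windows, so
  strongly correlated coefficient blocks (e.g. interaction designs) are
  effectively whitened;
* path lengths are jittered uniformly up to `trajectory_length / step`
  (default trajectory 2.5, capped at 96 leapfrog steps).

The default configuration is 4 chains of 2000 iterations with the first
half discarded as warm-up.  A fit passes convergence gating when every
parameter has split-chain potential scale reduction factor below 1.05 and
effective sample size above 100.  R-hat is the split-chain variant (a
deliberate strengthening over the classic estimator); the ESS uses Geyer's
initial monotone positive-pair truncation of the autocorrelation sum,
combined across split chains.  Both are implemented directly and
cross-checked against `arviz` in the test suite.  Impact evaluation
refuses unconverged fits unless forced.

Correctness of the sampler is established against independent oracles: 2-D
grid quadrature over (intercept, log dispersion) on intercept-only beta and
NB2 models (posterior means within 0.02, SDs within 10%), and prior-only
sampling reproducing the prior SDs within 5%.

## Effect metrics

For each post-intervention period, one outcome is simulated per retained
posterior draw from the family's observation distribution (not just the
fitted mean), so the forecast bands contain both parameter and observation
noise — the denominators of the ratio are full posterior-predictive draws.

* **Ratio**: equal-tailed sample quantiles (0.05, 0.25, 0.5, 0.75, 0.95) of
  `observed / predictive draw`.  NB2 predictive draws equal to zero would
  make the ratio infinite; they are excluded and counted (they are rare at
  the emulated import magnitudes).  Ratio summaries are invariant to
  rescaling observed and draws by a common factor.
* **Exceedance probability**: the fraction of predictive draws strictly
  below the observed value plus half the fraction exactly equal
  (mid-probability rule, unbiased for discrete counts).  Predictive draws
  rather than fitted-mean draws are used here too, matching the bands.

## Synthetic data

Real inputs of this kind (search-index panels, wholesaler counts, pooled
visitation) are proprietary or non-reproducible snapshots, so the package
generates panels with known ground truth; the generators are pure functions
of `(config, seed)` and every generated panel satisfies the panel
invariants.

**Search panels** (weekly, default 186 weeks, 6 references; the test
scenario uses 120 weeks, 3 references, intervention at week 105):
reference series are correlated AR(1) latent processes (persistence 0.85,
innovation SD 0.8, cross-correlation 0.5 via a shared innovation component)
pushed through a sharp low-shifted logistic map (scale 2.4, shift 1.5) and
normalized to their own maximum, the way search-index services deliver
series.  The shift and sharpness make the series sit at a small fraction of
their maximum most weeks with occasional steep correlated spikes — the
qualitative shape of real search-interest panels.  The focal mean is
`logit^{-1}(X beta)` with a low baseline (intercept −2.4) and
spike-capable slopes; observations are Beta(mu*phi, (1−mu)*phi) with
precision 50 (week-to-week CV ≈ 20% at typical levels).  Finally the focal
series is rescaled so its maximum is exactly 1.0.  This max-rescaling is a
real-data artifact the fitted model does not know about; the spiky defaults
keep the rescaling factor close to 1 (typical log factor ≈ 0.04), so
generative slopes remain recoverable — the parameter-recovery test measures
exactly this.

An injected effect multiplies the focal mean on the **odds** scale for the
beta family (so the mean stays inside the unit interval) and on the mean
scale for counts and visits.  The stored `mean_ratio` ground truth is the
implied ratio of means (for the beta family
`peak / (1 + (peak-1) mu)`, strictly below the odds peak), which is the
quantity the ratio metric estimates.  The default transient profile peaks
at the first post period and decays linearly to 1 by period 7.

**Import panels** (monthly, 24 months, 4 references, intervention at month
19): reference counts are NB2 around mildly seasonal log-means at the
hundreds-per-month scale with a shared month-to-month market factor; the
focal mean is `exp(X beta)` on the raw counts with slopes of order 1e-3 and
a baseline of ~8,300/month (of order 100,000/year), NB2 dispersion 12.
Optional decoy columns (~80% zeros) exercise the zero-dominated exclusion.

**Visitation series** (monthly, 132 months = 11 years): log-mean =
intercept (total ≈ 12M visits/year across institutions, i.e. ~10 in
100,000-visit units) + summer-peaked month effects (up to +0.55 in June)
+ a slow sinusoidal trend (amplitude 0.12 over the decade), residual SD
0.06.

What the generators deliberately do not emulate: search-index integer
quantization and region filtering, calendar irregularities, serially
correlated residuals, or reporting artifacts in visitation.  Passing
calibration on these panels shows the machinery is statistically sound
under the stated generative assumptions, not that any particular real
dataset satisfies them.

## Calibration harness and expected operating characteristics

`run_calibration_study` loops generate → evaluate and reports, per
scenario: mean/SD of the first-post-period exceedance probability, coverage
of the true mean ratio by the 90% ratio interval at that period, the
detection rate (`p_exceed > 0.9`), and the Kolmogorov–Smirnov distance of
the exceedance probabilities from Uniform(0, 1).  Under the null the
exceedance probabilities should be approximately uniform and the coverage
near 0.9; with the transient ×2.1 odds effect the week-1 ratio should be
recovered near its true mean-scale value (≈1.6–1.8 at the default levels)
and detection should be the norm.  Replicate and sampler seeds are derived
deterministically from the scenario seed.

The test suite and the acceptance script run these studies at 50 replicates
with reduced draws per fit (600–1000 iterations for the GLM families, 800
iterations with a longer trajectory for the seasonal model) — sizes chosen
so the whole suite completes on a single CPU while keeping Monte-Carlo
error well inside the asserted bands.

## Known limitations

* Counterfactual validity rests on the reference series being unaffected by
  the intervention; the package cannot check this.
* No autocorrelated error terms: residual dependence in real weekly series
  would make credible bands anti-conservative.
* The beta family requires the boundary substitution; series with many
  exact zeros deserve a zero-inflated model instead.
* Spline forecasts use linear extension; long forecast horizons far beyond
  the fitted range will understate trend curvature uncertainty.
* The NB2 import model includes no seasonal terms (a two-year monthly
  series cannot identify them separately from the references).
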