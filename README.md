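# countercast

Bayesian posterior-predictive counterfactual evaluation of interventions on
time series.

A recurring question in conservation science, epidemiology and policy
evaluation: did a discrete event — a blockbuster movie featuring a species,
a media campaign, a regulation — change a measured behaviour?  A before/
after comparison is confounded by seasonality, trends and shared shocks.
`countercast` implements the counterfactual alternative: fit a regression
model **only to pre-intervention data**, project what the series would have
looked like without the intervention from the posterior-predictive
distribution, and compare the observed values to that forecast.

Three observation models cover the outcome kinds that arise across a
purchase-funnel-style set of indicators (information seeking → substitute
activity → purchase):

| family | outcome | model |
|---|---|---|
| `beta` | relative search frequency in (0, 1) | y ~ Beta(μ, φ), logit(μ) = Xβ; X = reference series + pairwise interactions |
| `negbin` | monthly import counts | y ~ NB2(μ, φ), log(μ) = Xβ; variance μ + μ²/φ |
| `seasonal_trend` | monthly visitation (100,000-visit units) | log(y) ~ Normal(μ, σ²), μ = month factor + penalized spline over standardized time |

with weakly informative priors — Normal(0, 10) intercept, Normal(0, 2)
slopes, half-Student-t(3, 0, 25) on φ and half-Student-t(3, 0, 2) on σ and
the spline wiggliness SD.  Models are fit by a built-in gradient-based
Hamiltonian Monte Carlo sampler (4 chains × 2000 iterations, first half
warm-up, by default) and gated on convergence: split-chain R̂ < 1.05 and
n_eff > 100 for every parameter.

The impact of the intervention is reported per post-intervention period as

* the ratio of observed to posterior-predictive outcome (median, 50% and
  90% equal-tailed credible intervals) — values above 1 mean a higher than
  expected outcome; and
* the exceedance probability — the posterior-predictive probability that
  the observed value is higher than expected.

Because real inputs of this kind are typically proprietary, the package
ships first-class synthetic-data generators with known ground truth for all
three panel kinds, plus a calibration harness that verifies the framework's
statistical operating characteristics (uniform null exceedance
probabilities, nominal interval coverage, detection of injected effects).

## Worked example

`examples/01_search_impact.py` generates a 120-week panel of relative
search-interest series (one focal, three references), injects a transient
effect at week 105 — the odds of the focal mean doubled at week 1, decaying
to nothing by week 7 — and runs the full pipeline:

```
panel: 120 weeks, intervention 2016-01-03
true week-1 ratio of means: 1.76
convergence PASSED: max R-hat 1.0022 (intercept), min n_eff 1304 (ref_03)

week 1 after the intervention:
  observed relative frequency : 0.293
  counterfactual median       : 0.124
  observed/expected ratio     : 2.37 (90% CI 1.42-4.67)
  P(higher than expected)     : 1.00
```

The fitted ratio (2.37, with bands reflecting both parameter and
observation noise) brackets the true generative ratio of 1.76, the
exceedance probability flags the injected spike, and in the full table
the signal decays back toward ratio ≈ 1 and p ≈ 0.5 over the following
weeks — the behaviour a transient effect should produce.

The other examples cover the count model with automatic exclusion of
zero-dominated reference series (`02_import_counts.py`), the seasonal
visitation model (`03_visits_seasonal.py`), and the calibration harness
(`04_calibration.py`).

## Command line

```sh
countercast simulate --kind search --n 120 --k 3 --intervention-index 104 \
    --effect-peak 2.0 --seed 7 --out panel.csv      # + panel.truth sidecar
countercast evaluate --panel panel.csv --family beta \
    --intervention-date 2016-01-03 --seed 1 --out-dir run/
countercast calibrate --kind imports --replicates 20 --seed 1 --out cal.csv
```

`evaluate` writes the impact summary CSV, the convergence report, the
pre-period predictive bands, a run log and the effective configuration
(YAML), so a run is reproducible from its outputs alone.

## Layout

```
src/countercast/
  panel.py          # panels, intervention studies, deterministic transforms
  models.py         # likelihoods, designs, priors, spline basis
  sampling.py       # HMC sampler (dense metric, dual averaging)
  diagnostics.py    # split R-hat, ESS, convergence gating
  impact.py         # posterior-predictive forecasting + effect metrics
  simulate.py       # synthetic panels with ground truth, calibration harness
  cli.py            # simulate / evaluate / calibrate subcommands
docs/methods.md     # modelling and design notes
examples/           # narrative scripts, one per capability
```
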