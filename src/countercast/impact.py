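"""Posterior-predictive counterfactual forecasting and effect metrics.

The counterfactual logic: fit the family model to the strictly
pre-intervention rows, push every retained posterior draw through the
inverse link at the post-intervention design points, and simulate one
outcome per draw from the observation distribution.  The resulting
posterior-predictive draws are the "what would have happened" distribution;
the effect metrics compare each observed post-intervention value against it:

* the **ratio** of observed to predicted outcome, summarized by its median
  and equal-tailed 50%/90% credible intervals (values above 1 mean a higher
  than expected outcome), and
* the **exceedance probability** — the posterior-predictive probability that
  the observed value is higher than expected.

The predictive draws include both parameter and observation noise, so the
bands reflect the full predictive uncertainty, not just the fitted mean.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .diagnostics import ConvergenceError, ConvergenceReport, check_convergence
from .models import (DesignMatrix, Family, ModelSpec, SplineBasis,
                     build_import_design, build_month_design,
                     build_search_design, exclude_zero_dominated,
                     zero_dominated_references)
from .panel import (InterventionStudy, OutcomeKind, TimeSeriesPanel,
                    rescale_relative, split_pre_post, standardize_time,
                    substitute_unit_boundary)
from .sampling import PosteriorSamples, SamplerConfig, sample_posterior

__all__ = [
    "PredictiveDistribution",
    "RatioSummary",
    "ImpactResult",
    "posterior_predict",
    "effect_ratio",
    "exceedance_probability",
    "evaluate_impact",
    "prepare_study",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("date", "observed", "expected_median", "ratio_median",
                   "ratio_lo50", "ratio_hi50", "ratio_lo90", "ratio_hi90",
                   "p_exceed")


@dataclass(frozen=True)
class PredictiveDistribution:
    """Per-time-point posterior-predictive outcome draws (observation scale)."""

    times: Tuple[_dt.date, ...]
    draws: np.ndarray          # (n_draws, n_times)
    outcome_kind: OutcomeKind

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.times):
            raise ValueError("draws must be (n_draws, n_times)")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def quantiles(self, qs) -> np.ndarray:
        return np.quantile(self.draws, qs, axis=0)


@dataclass(frozen=True)
class RatioSummary:
    """Observed/expected ratio quantiles for one time point."""

    median: float
    ci50: Tuple[float, float]
    ci90: Tuple[float, float]
    n_zero_dropped: int = 0


def posterior_predict(samples: PosteriorSamples, spec: ModelSpec,
                      post_design: DesignMatrix, rng_seed: int,
                      times=None, basis: Optional[np.ndarray] = None,
                      ) -> PredictiveDistribution:
    """Simulate one outcome per posterior draw at each design point.

    For each retained draw the linear predictor is pushed through the
    family's inverse link and one observation is simulated: Beta(mu*phi,
    (1-mu)*phi) for searches, NB2(mu, phi) for imports, and
    exp(Normal(mu_log, sigma)) on the visits scale for the seasonal model
    (pass the spline ``basis`` evaluated at the prediction times, built with
    the pre-period standardization constants).
    """
    missing = [n for n in post_design.names if n not in samples.draws]
    if missing:
        raise ValueError(f"post design columns not in posterior: {missing}")
    coefs = samples.flat_matrix(post_design.names)          # (d, p)
    eta = coefs @ post_design.X.T                           # (d, T)
    rng = np.random.default_rng(rng_seed)
    family = Family(spec.family)
    if family is Family.beta:
        phi = samples.flat("phi")[:, None]
        mu = special.expit(eta)
        draws = rng.beta(mu * phi, (1.0 - mu) * phi)
        tiny = np.finfo(float).tiny
        draws = np.clip(draws, tiny, 1.0 - 1e-16)
        kind = OutcomeKind.proportion
    elif family is Family.negbin:
        phi = samples.flat("phi")[:, None]
        mu = np.exp(np.clip(eta, -500, 500))
        # gamma-Poisson mixture form of NB2; stable for very large phi draws
        lam = rng.gamma(shape=np.broadcast_to(phi, mu.shape), scale=mu / phi)
        lam = np.minimum(lam, 1e15)   # guard: keep extreme tail draws finite
        draws = rng.poisson(lam).astype(float)
        kind = OutcomeKind.count
    else:
        if basis is None:
            raise ValueError("seasonal_trend prediction requires the spline "
                             "basis at the prediction times")
        snames = [n for n in samples.parameter_names if n.startswith("s_")]
        if basis.shape[1] != len(snames):
            raise ValueError("basis columns do not match spline coefficients")
        scoef = samples.flat_matrix(snames)
        mu_log = eta + scoef @ basis.T
        sigma = samples.flat("sigma")[:, None]
        draws = np.exp(rng.normal(mu_log, sigma))
        kind = OutcomeKind.positive_real
    if times is None:
        times = tuple(range(post_design.n))
    return PredictiveDistribution(times=tuple(times), draws=draws,
                                  outcome_kind=kind)


def effect_ratio(observed: float, predictive_draws) -> RatioSummary:
    """Quantiles of the observed/predicted ratio distribution.

    Equal-tailed sample quantiles (0.05, 0.25, 0.5, 0.75, 0.95) of
    ``observed / draw``.  Count draws equal to zero would make the ratio
    infinite; they are excluded and their number recorded (they are rare at
    realistic import magnitudes and do not enter the exceedance metric).
    """
    draws = np.asarray(predictive_draws, dtype=float)
    nonzero = draws != 0
    n_dropped = int((~nonzero).sum())
    draws = draws[nonzero]
    if draws.size == 0:
        raise ValueError("all predictive draws are zero; ratio undefined")
    if n_dropped:
        logger.warning("effect_ratio: dropped %d zero predictive draw(s)",
                       n_dropped)
    ratios = observed / draws
    lo90, lo50, med, hi50, hi90 = np.quantile(ratios,
                                              [0.05, 0.25, 0.5, 0.75, 0.95])
    return RatioSummary(median=float(med), ci50=(float(lo50), float(hi50)),
                        ci90=(float(lo90), float(hi90)),
                        n_zero_dropped=n_dropped)


def exceedance_probability(observed: float, predictive_draws) -> float:
    """Posterior-predictive probability of a higher-than-expected outcome.

    The fraction of predictive draws strictly below the observed value plus
    half the fraction exactly equal to it (mid-probability rule, so discrete
    count outcomes are handled without bias).
    """
    draws = np.asarray(predictive_draws, dtype=float)
    below = float(np.mean(draws < observed))
    ties = float(np.mean(draws == observed))
    return below + 0.5 * ties


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PreparedStudy:
    """Preprocessed pre/post panels and designs, ready to fit and forecast."""

    pre: TimeSeriesPanel
    post: TimeSeriesPanel
    design_pre: DesignMatrix
    design_post: DesignMatrix
    y_pre: np.ndarray
    y_post: np.ndarray
    basis_pre: Optional[np.ndarray] = None
    basis_post: Optional[np.ndarray] = None
    dropped_references: Tuple[str, ...] = ()
    n_boundary_substitutions: int = 0
    n_design_columns: int = 0


def prepare_study(study: InterventionStudy, spec: ModelSpec) -> PreparedStudy:
    """Run the family's deterministic preprocessing and build designs.

    * beta: rescale 0-100 indices to proportions, substitute 0.99 for the
      maximum (1.0) week and eps for exact zeros on the focal series, then
      build the interaction design.
    * negbin: drop zero-dominated reference series, main-effects design.
    * seasonal_trend: decimal dates standardized on the pre-period only;
      month-factor design plus the centred spline basis (linearly extended
      beyond the fitted range for forecasting).
    """
    panel = study.panel
    family = Family(spec.family)
    expected_kind = {Family.beta: OutcomeKind.proportion,
                     Family.negbin: OutcomeKind.count,
                     Family.seasonal_trend: OutcomeKind.positive_real}[family]
    if panel.outcome_kind is not expected_kind:
        raise TypeError(
            f"family {family.value} requires outcome_kind "
            f"{expected_kind.value}, got {panel.outcome_kind.value}"
        )
    dropped: Tuple[str, ...] = ()
    n_sub = 0
    if family is Family.beta:
        focal = rescale_relative(panel.focal)
        boundary = int(np.sum((focal == 0.0) | (focal == 1.0)))
        focal = substitute_unit_boundary(focal)
        n_sub = boundary
        refs = {n: rescale_relative(v) for n, v in panel.references.items()}
        panel = TimeSeriesPanel(panel.times, focal, refs, panel.frequency,
                                panel.outcome_kind)
    elif family is Family.negbin:
        dropped = zero_dominated_references(panel, spec.zero_threshold)
        panel = exclude_zero_dominated(panel, spec.zero_threshold)
    study = InterventionStudy(panel, study.intervention_date)
    pre, post = split_pre_post(study)

    basis_pre = basis_post = None
    if family is Family.beta:
        design_pre = build_search_design(pre)
        design_post = build_search_design(post)
        n_cols = design_pre.p
    elif family is Family.negbin:
        design_pre = build_import_design(pre)
        design_post = build_import_design(post)
        n_cols = design_pre.p
    else:
        st = standardize_time(pre.times, fit_dates=pre.times)
        sb = SplineBasis(st.values, num_basis=spec.num_basis)
        st_post = standardize_time(post.times, fit_dates=pre.times)
        basis_pre = sb.random_part(st.values)
        basis_post = sb.random_part(st_post.values)
        # month factor + the smooth's unpenalized linear trend column
        md_pre = build_month_design(pre.times)
        md_post = build_month_design(post.times)
        design_pre = DesignMatrix(names=md_pre.names + ("trend",),
                                  X=np.column_stack([md_pre.X, st.values]))
        design_post = DesignMatrix(names=md_post.names + ("trend",),
                                   X=np.column_stack([md_post.X,
                                                      st_post.values]))
        n_cols = design_pre.p + sb.num_random
    study.require_identifiable(n_cols)
    return PreparedStudy(pre=pre, post=post, design_pre=design_pre,
                         design_post=design_post, y_pre=pre.focal,
                         y_post=post.focal, basis_pre=basis_pre,
                         basis_post=basis_post, dropped_references=dropped,
                         n_boundary_substitutions=n_sub,
                         n_design_columns=n_cols)


@dataclass
class ImpactResult:
    """Everything the counterfactual evaluation produces."""

    summary: pd.DataFrame
    convergence: ConvergenceReport
    samples: PosteriorSamples
    predictive: PredictiveDistribution
    pre_bands: pd.DataFrame
    prepared: PreparedStudy

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _summarize(times, observed, predictive: PredictiveDistribution
               ) -> pd.DataFrame:
    rows = []
    for j, (t, obs) in enumerate(zip(times, observed)):
        draws = predictive.draws[:, j]
        ratio = effect_ratio(obs, draws)
        rows.append({
            "date": t.isoformat(),
            "observed": float(obs),
            "expected_median": float(np.median(draws)),
            "ratio_median": ratio.median,
            "ratio_lo50": ratio.ci50[0],
            "ratio_hi50": ratio.ci50[1],
            "ratio_lo90": ratio.ci90[0],
            "ratio_hi90": ratio.ci90[1],
            "p_exceed": exceedance_probability(obs, draws),
        })
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def evaluate_impact(study: InterventionStudy, spec: ModelSpec,
                    sampler: SamplerConfig, force: bool = False
                    ) -> ImpactResult:
    """The full counterfactual pipeline for one study.

    Splits the panel, preprocesses, fits the family model to the pre-period
    only, forecasts the post-period from the posterior-predictive
    distribution, and tabulates per-time-point ratio summaries and
    exceedance probabilities.  Pre-period predictive bands are evaluated as
    well, for display of model fit.  Unconverged fits raise
    :class:`ConvergenceError` unless ``force`` is set.
    """
    prepared = prepare_study(study, spec)
    samples = sample_posterior(spec, prepared.design_pre, prepared.y_pre,
                               sampler, basis=prepared.basis_pre)
    report = check_convergence(samples)
    if not report.passed:
        if not force:
            raise ConvergenceError(report)
        logger.warning("proceeding on unconverged fit (force=True): %s",
                       report.summary())
    predictive = posterior_predict(samples, spec, prepared.design_post,
                                   rng_seed=sampler.seed + 1,
                                   times=prepared.post.times,
                                   basis=prepared.basis_post)
    summary = _summarize(prepared.post.times, prepared.y_post, predictive)
    pre_pred = posterior_predict(samples, spec, prepared.design_pre,
                                 rng_seed=sampler.seed + 2,
                                 times=prepared.pre.times,
                                 basis=prepared.basis_pre)
    qs = pre_pred.quantiles([0.05, 0.25, 0.5, 0.75, 0.95])
    pre_bands = pd.DataFrame({
        "date": [t.isoformat() for t in prepared.pre.times],
        "observed": prepared.y_pre,
        "lo90": qs[0], "lo50": qs[1], "median": qs[2],
        "hi50": qs[3], "hi90": qs[4],
    })
    return ImpactResult(summary=summary, convergence=report, samples=samples,
                        predictive=predictive, pre_bands=pre_bands,
                        prepared=prepared)
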