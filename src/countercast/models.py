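"""The three counterfactual model families as explicit likelihood definitions.

Three observation models cover the three outcome kinds:

* **beta** — relative search frequencies ``y_i ~ Beta(mu_i, phi)`` in the
  mean-precision parameterization (shapes ``p = mu*phi``, ``q = (1-mu)*phi``)
  with ``logit(mu_i) = X_i beta`` and a design of reference main effects plus
  all pairwise interactions.
* **negbin** — import counts ``y_i ~ NB2(mu_i, phi)`` with
  ``log(mu_i) = X_i beta``, variance ``mu + mu**2/phi``, and a main-effects
  design of reference counts.
* **seasonal_trend** — ``log(y_i) ~ Normal(mu_i, sigma**2)`` with
  ``mu_i = M_i beta_1 + s(T_i)``: a January-base month factor plus a
  penalized cubic B-spline smooth over standardized decimal time.

All families share the weakly informative prior scheme: Normal(0, 10) on the
intercept, Normal(0, 2) on every other coefficient, and a half-Student-t
(df 3) on the positive dispersion parameters — scale 25 for the beta/NB2
precision ``phi`` and scale 2 for the residual SD ``sigma`` and the spline
wiggliness SD.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import interpolate, stats

from .panel import TimeSeriesPanel

__all__ = [
    "Family",
    "PriorSet",
    "DesignMatrix",
    "ModelSpec",
    "ParameterVector",
    "beta_shapes_from_mean_precision",
    "beta_loglik",
    "negbin_loglik",
    "seasonal_trend_loglik",
    "build_search_design",
    "build_import_design",
    "build_month_design",
    "zero_dominated_references",
    "exclude_zero_dominated",
    "SplineBasis",
    "spline_basis",
    "log_prior",
]

logger = logging.getLogger(__name__)


class Family(str, enum.Enum):
    beta = "beta"
    negbin = "negbin"
    seasonal_trend = "seasonal_trend"


@dataclass(frozen=True)
class PriorSet:
    """Weakly informative prior scales shared by the three families."""

    slope_scale: float = 2.0
    intercept_scale: float = 10.0
    dispersion_df: float = 3.0
    dispersion_scale: float = 25.0   # phi for beta/negbin; 2 for sigma
    spline_sd_scale: float = 2.0     # wiggliness SD, seasonal_trend only

    def __post_init__(self):
        for name in ("slope_scale", "intercept_scale", "dispersion_df",
                     "dispersion_scale", "spline_sd_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DesignMatrix:
    names: Tuple[str, ...]
    X: np.ndarray
    includes_intercept: bool = True

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match column names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("design column names must be unique")
        if len(self.names) < 1:
            raise ValueError("design matrix needs at least one column")
        if self.includes_intercept and X.shape[0] > 0 and not np.all(X[:, 0] == 1.0):
            raise ValueError("first column must be all ones when includes_intercept")

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ModelSpec:
    """Family + prior set + (for the seasonal model) spline configuration."""

    family: Family
    priors: PriorSet
    num_basis: int = 10
    zero_threshold: float = 0.5

    @classmethod
    def for_family(cls, family, num_basis: int = 10,
                   zero_threshold: float = 0.5) -> "ModelSpec":
        """Construct with each family's default prior scales."""
        family = Family(family)
        disp_scale = 2.0 if family is Family.seasonal_trend else 25.0
        return cls(family=family, priors=PriorSet(dispersion_scale=disp_scale),
                   num_basis=num_basis, zero_threshold=zero_threshold)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "priors": {
                "slope_scale": self.priors.slope_scale,
                "intercept_scale": self.priors.intercept_scale,
                "dispersion_df": self.priors.dispersion_df,
                "dispersion_scale": self.priors.dispersion_scale,
                "spline_sd_scale": self.priors.spline_sd_scale,
            },
            "num_basis": self.num_basis,
            "zero_threshold": self.zero_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(family=Family(d["family"]), priors=PriorSet(**d["priors"]),
                   num_basis=int(d.get("num_basis", 10)),
                   zero_threshold=float(d.get("zero_threshold", 0.5)))


@dataclass(frozen=True)
class ParameterVector:
    """One point in parameter space, on the constrained scale."""

    coefficients: np.ndarray
    dispersion: float                      # phi (beta/negbin) or sigma
    spline_coeffs: Optional[np.ndarray] = None
    spline_sd: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float))
        if self.spline_coeffs is not None:
            object.__setattr__(self, "spline_coeffs",
                               np.asarray(self.spline_coeffs, dtype=float))
            if self.spline_sd is None:
                raise ValueError("spline_coeffs given without spline_sd")


# ---------------------------------------------------------------------------
# likelihoods


def beta_shapes_from_mean_precision(mu, phi):
    """Mean-precision (mu, phi) -> classical beta shapes (p, q).

    ``p = mu*phi``, ``q = (1-mu)*phi`` so that ``mu = p/(p+q)`` and
    ``phi = p + q`` exactly.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if not np.all(np.asarray(phi) > 0):
        raise ValueError("phi must be > 0")
    return mu * phi, (1.0 - mu) * phi


def beta_loglik(y, mu, phi) -> float:
    """Sum of log Beta(mu_i, phi) densities (mean-precision form)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have equal lengths")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError(
            "beta_loglik requires y strictly inside (0, 1); apply "
            "substitute_unit_boundary to boundary values first"
        )
    p, q = beta_shapes_from_mean_precision(mu, phi)
    return float(np.sum(stats.beta.logpdf(y, p, q)))


def negbin_loglik(y, mu, phi) -> float:
    """Sum of NB2 log pmfs with mean ``mu_i`` and dispersion ``phi``.

    Variance is ``mu + mu**2/phi``; as ``phi -> inf`` the pmf converges to
    the Poisson pmf with the same mean.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("negbin_loglik requires non-negative integer y")
    if not np.all(mu > 0) or not phi > 0:
        raise ValueError("mu and phi must be positive")
    return float(np.sum(stats.nbinom.logpmf(np.round(y).astype(int),
                                            phi, phi / (phi + mu))))


def seasonal_trend_loglik(y, month_index, t_std, params: ParameterVector,
                          basis: np.ndarray) -> float:
    """Gaussian log-likelihood of log(y) around month effects + spline.

    ``params.coefficients`` is ``[intercept, beta_feb, ..., beta_dec]``
    (January is the base month with coefficient 0); the spline contribution
    is ``basis @ params.spline_coeffs``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("seasonal_trend_loglik requires strictly positive y")
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != y.shape[0]:
        raise ValueError("basis rows must match length of y")
    M = _month_dummies(np.asarray(month_index, dtype=int))
    coefs = params.coefficients
    if coefs.shape[0] != 12:
        raise ValueError("expected 12 coefficients: intercept + 11 months")
    mu = coefs[0] + M @ coefs[1:]
    if params.spline_coeffs is not None:
        mu = mu + basis @ params.spline_coeffs
    sigma = params.dispersion
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return float(np.sum(stats.norm.logpdf(np.log(y), mu, sigma)))


def _month_dummies(month_index: np.ndarray) -> np.ndarray:
    """(n, 11) dummy matrix for months Feb..Dec; January rows are all zero."""
    if np.any(month_index < 1) or np.any(month_index > 12):
        raise ValueError("month_index must be in 1..12")
    M = np.zeros((month_index.shape[0], 11))
    for j in range(2, 13):
        M[month_index == j, j - 2] = 1.0
    return M


# ---------------------------------------------------------------------------
# design matrices


def build_search_design(panel: TimeSeriesPanel) -> DesignMatrix:
    """Intercept + reference main effects + all pairwise interactions.

    Reference columns are taken in name-sorted order; interaction columns
    ``a:b`` (a < b) follow the mains, also name-sorted.  With k references
    the design has ``1 + k + k(k-1)/2`` columns.
    """
    names = sorted(panel.reference_names)
    if not names:
        raise ValueError("search design needs at least one reference series")
    cols = [np.ones(len(panel))]
    colnames = ["intercept"]
    for name in names:
        cols.append(panel.references[name])
        colnames.append(name)
    for a, b in itertools.combinations(names, 2):
        cols.append(panel.references[a] * panel.references[b])
        colnames.append(f"{a}:{b}")
    return DesignMatrix(names=tuple(colnames), X=np.column_stack(cols))


def build_import_design(panel: TimeSeriesPanel) -> DesignMatrix:
    """Intercept + reference main effects only (no interactions)."""
    names = list(panel.reference_names)
    if not names:
        raise ValueError("import design needs at least one reference series")
    cols = [np.ones(len(panel))] + [panel.references[n] for n in names]
    return DesignMatrix(names=tuple(["intercept"] + names),
                        X=np.column_stack(cols))


def build_month_design(dates: Sequence) -> DesignMatrix:
    """Intercept + 11 month dummies (January base) from calendar dates."""
    months = np.array([d.month for d in dates], dtype=int)
    M = _month_dummies(months)
    names = ["intercept"] + [f"month_{m}" for m in range(2, 13)]
    return DesignMatrix(names=tuple(names),
                        X=np.column_stack([np.ones(len(months)), M]))


def zero_dominated_references(panel: TimeSeriesPanel,
                              threshold: float = 0.5) -> Tuple[str, ...]:
    """Names of reference columns whose zero fraction exceeds ``threshold``."""
    out = []
    for name, col in panel.references.items():
        if np.mean(col == 0) > threshold:
            out.append(name)
    return tuple(out)


def exclude_zero_dominated(panel: TimeSeriesPanel,
                           threshold: float = 0.5) -> TimeSeriesPanel:
    """Drop reference series overwhelmingly dominated by zeros.

    Count series that are mostly zeros carry almost no counterfactual signal
    and destabilize the log-link fit, so any reference whose fraction of
    exact zeros exceeds ``threshold`` is removed (and logged).
    """
    dropped = zero_dominated_references(panel, threshold)
    if dropped:
        logger.info("excluding zero-dominated reference series: %s",
                    ", ".join(dropped))
    kept = {n: v for n, v in panel.references.items() if n not in dropped}
    if not kept:
        raise ValueError("all reference series are zero-dominated")
    return panel.with_references(kept)


# ---------------------------------------------------------------------------
# penalized spline basis


class SplineBasis:
    """Penalized cubic B-spline smooth in mixed-model form.

    The smooth is built from ``num_basis`` cubic B-splines on equally spaced
    clamped knots spanning the fitting ``t_std`` range, with a second-order
    difference penalty on the coefficients.  It is re-parameterized the way
    mixed-model smoothers (mgcv-style) are: the penalty null space — the
    constant and linear parts — is split off as unpenalized fixed effects
    (the constant is absorbed by the model intercept; the linear trend is a
    design column with the ordinary slope prior), and the wiggly remainder
    becomes ``num_basis - 2`` exchangeable random-effect columns whose
    coefficients share a single Normal(0, spline_sd) prior.  The one
    ``spline_sd`` hyperparameter therefore controls exactly the wiggliness
    of the smooth, not its level or slope.

    Forecast times beyond the fitted range are handled by linear extension:
    every basis column is continued from its boundary value with its
    boundary slope, so the smooth extrapolates as a straight line rather
    than oscillating.
    """

    def __init__(self, t_fit: np.ndarray, num_basis: int = 10):
        t_fit = np.asarray(t_fit, dtype=float)
        if num_basis < 4:
            raise ValueError("num_basis must be at least 4 for cubic splines")
        if not np.all(np.isfinite(t_fit)):
            raise ValueError("t_std must be finite")
        lo, hi = float(t_fit.min()), float(t_fit.max())
        if hi <= lo:
            raise ValueError("fitting times are degenerate")
        self.num_basis = int(num_basis)
        self.num_random = int(num_basis) - 2
        self.lo, self.hi = lo, hi
        interior = np.linspace(lo, hi, num_basis - 2)
        self.knots = np.concatenate([[lo] * 3, interior, [hi] * 3])
        self._value_hi = self._raw_inside(np.array([hi]))[0]
        self._value_lo = self._raw_inside(np.array([lo]))[0]
        self._slope_hi = self._boundary_slope(hi)
        self._slope_lo = self._boundary_slope(lo)
        # mixed-model map: coefficients = D'(DD')^{-1} u have penalty ||u||^2
        K = self.num_basis
        D = np.diff(np.eye(K), n=2, axis=0)          # (K-2, K)
        self._to_coef = D.T @ np.linalg.inv(D @ D.T)  # (K, K-2)
        # project the random part out of the [1, t] fixed space on the
        # fitting points, and freeze the projection for prediction
        self.t_fit = t_fit
        F = np.column_stack([np.ones_like(t_fit), t_fit])
        Z_fit = self.raw(t_fit) @ self._to_coef
        self._proj, *_ = np.linalg.lstsq(F, Z_fit, rcond=None)   # (2, K-2)

    def _raw_inside(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.lo, self.hi)
        # design_matrix is exclusive of the right endpoint's last interval edge
        x = np.minimum(x, np.nextafter(self.hi, self.lo))
        return interpolate.BSpline.design_matrix(x, self.knots, 3).toarray()

    def _boundary_slope(self, x0: float) -> np.ndarray:
        slopes = np.empty(self.num_basis)
        for j in range(self.num_basis):
            c = np.zeros(self.num_basis)
            c[j] = 1.0
            slopes[j] = interpolate.BSpline(self.knots, c, 3,
                                            extrapolate=False).derivative()(
                np.clip(x0, self.lo, np.nextafter(self.hi, self.lo)))
        return slopes

    def raw(self, x) -> np.ndarray:
        """Un-centred B-spline basis; rows sum to 1 inside the fitted range."""
        x = np.asarray(x, dtype=float)
        B = self._raw_inside(x)
        above = x > self.hi
        below = x < self.lo
        if above.any():
            B[above] = self._value_hi + np.outer(x[above] - self.hi, self._slope_hi)
        if below.any():
            B[below] = self._value_lo + np.outer(x[below] - self.lo, self._slope_lo)
        return B

    def random_part(self, x) -> np.ndarray:
        """(n, num_basis - 2) penalized columns, orthogonal to 1 and t on
        the fitting points; linearly extended outside the fitted range."""
        x = np.asarray(x, dtype=float)
        Z = self.raw(x) @ self._to_coef
        F = np.column_stack([np.ones_like(x), x])
        return Z - F @ self._proj

    # kept name from earlier iterations of the API
    def centered(self, x) -> np.ndarray:
        return self.random_part(x)


def spline_basis(t_std, num_basis: int = 10) -> Tuple[np.ndarray, dict]:
    """Mixed-model spline basis plus a description of its penalty.

    Returns the (n, num_basis - 2) random-effect basis evaluated at
    ``t_std`` and a dictionary describing the smoothness prior: the penalty
    null space (constant + linear trend) is carried by the intercept and a
    linear design column, and the returned columns have exchangeable
    Normal(0, spline_sd) coefficients with spline_sd ~ half-Student-t(3, 2).
    """
    t_std = np.asarray(t_std, dtype=float)
    sb = SplineBasis(t_std, num_basis=num_basis)
    penalty = {
        "kind": "second-difference (mixed-model form)",
        "coefficient_prior": "Normal(0, spline_sd)",
        "spline_sd_prior": "half-Student-t(df=3, scale=2)",
        "basis": "cubic B-spline, clamped uniform knots; null space "
                 "(constant, linear) removed into fixed effects",
        "num_basis": int(num_basis),
        "num_random_columns": sb.num_random,
    }
    return sb.random_part(t_std), penalty


# ---------------------------------------------------------------------------
# priors


def _half_student_t_logpdf(x: float, df: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log(2.0) + stats.t.logpdf(x, df, scale=scale))


def log_prior(params: ParameterVector, priors: PriorSet) -> float:
    """Joint log prior density at ``params``.

    Normal(0, intercept_scale) on the first coefficient, Normal(0,
    slope_scale) on the rest, half-Student-t on the dispersion and (when
    present) on the spline SD, with Normal(0, spline_sd) on the spline
    coefficients.  Non-positive dispersion yields ``-inf`` rather than an
    exception so samplers can treat it as zero posterior mass.
    """
    coefs = params.coefficients
    lp = float(stats.norm.logpdf(coefs[0], 0.0, priors.intercept_scale))
    if coefs.shape[0] > 1:
        lp += float(np.sum(stats.norm.logpdf(coefs[1:], 0.0, priors.slope_scale)))
    lp += _half_student_t_logpdf(params.dispersion, priors.dispersion_df,
                                 priors.dispersion_scale)
    if params.spline_coeffs is not None:
        lp += _half_student_t_logpdf(params.spline_sd, priors.dispersion_df,
                                     priors.spline_sd_scale)
        if np.isfinite(lp):
            lp += float(np.sum(stats.norm.logpdf(params.spline_coeffs, 0.0,
                                                 params.spline_sd)))
    return lp
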