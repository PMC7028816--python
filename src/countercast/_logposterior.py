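"""Unnormalized log posteriors with analytic gradients, for the HMC sampler.

Each class maps an unconstrained parameter vector ``theta`` to
``log p(theta | y) + const`` and its gradient.  Positive parameters (the
beta/NB2 precision ``phi``, the residual SD ``sigma`` and the spline
wiggliness SD) are represented on the log scale with the Jacobian term
included, so the sampler sees an unconstrained space throughout.

The seasonal model uses a non-centred spline parameterization: the sampler
works with standard-normal ``z`` and the wiggliness SD ``tau``, and the
spline coefficients reported downstream are ``tau * z``.  This removes the
funnel geometry between the coefficients and their SD.

Parameter layouts
-----------------
GLM (beta / negbin):    ``[coefficients (p), log phi]``
seasonal_trend:         ``[intercept, month_2..month_12, z (K), log sigma,
                          log tau]``
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
from scipy import special

from .models import DesignMatrix, Family, ModelSpec, ParameterVector, PriorSet

__all__ = ["GlmLogPosterior", "SeasonalLogPosterior", "build_log_posterior"]

_LOG2PI = math.log(2.0 * math.pi)


def _normal_lp_grad(x: np.ndarray, scale: float) -> Tuple[float, np.ndarray]:
    lp = float(np.sum(-0.5 * (x / scale) ** 2 - math.log(scale) - 0.5 * _LOG2PI))
    return lp, -x / scale**2


def _half_t_lp_grad(x: float, df: float, scale: float) -> Tuple[float, float]:
    """log density of |Student-t(df, 0, scale)| at x > 0, and d/dx."""
    const = (special.gammaln((df + 1) / 2) - special.gammaln(df / 2)
             - 0.5 * math.log(df * math.pi) - math.log(scale) + math.log(2.0))
    lp = const - (df + 1) / 2 * math.log1p(x**2 / (df * scale**2))
    grad = -(df + 1) * x / (df * scale**2 + x**2)
    return float(lp), float(grad)


def _half_t_median(df: float, scale: float) -> float:
    from scipy import stats
    return float(scale * stats.t.ppf(0.75, df))


def _column_scales(X: np.ndarray) -> np.ndarray:
    """Per-column scaling for the sampler's internal parameterization.

    Coefficients of columns with very different magnitudes (e.g. raw count
    predictors) are sampled as ``u_j = beta_j * s_j`` with ``s_j`` the
    column SD, which equalizes their posterior scales.  Constant or empty
    columns keep ``s_j = 1``.  The transformation is invisible outside the
    sampler: draws are mapped back to the original coefficients.
    """
    if X.shape[0] < 2:
        return np.ones(X.shape[1])
    s = np.std(X, axis=0)
    s[~np.isfinite(s) | (s == 0)] = 1.0
    return s


def _coef_prior_scales(p: int, priors: PriorSet, s: np.ndarray) -> np.ndarray:
    """Prior SDs for the scaled coefficients u_j = beta_j * s_j."""
    scales = np.full(p, priors.slope_scale)
    scales[0] = priors.intercept_scale
    return scales * s


def _normal_vec_lp_grad(u: np.ndarray, scales: np.ndarray):
    lp = float(np.sum(-0.5 * (u / scales) ** 2 - np.log(scales)
                      - 0.5 * _LOG2PI))
    return lp, -u / scales**2


class GlmLogPosterior:
    """Beta or NB2 regression posterior on ``[beta, log phi]``."""

    def __init__(self, family: Family, design: DesignMatrix, y: np.ndarray,
                 priors: PriorSet):
        self.family = Family(family)
        if self.family not in (Family.beta, Family.negbin):
            raise ValueError("GlmLogPosterior handles beta/negbin only")
        self.design = design
        self.y = np.asarray(y, dtype=float)
        if design.X.shape[0] != self.y.shape[0]:
            raise ValueError("design rows must match length of y")
        self.priors = priors
        self.p = design.p
        self.dim = self.p + 1
        self.names: List[str] = list(design.names) + ["phi"]
        self.scales = _column_scales(design.X)
        self.X = design.X / self.scales
        self._coef_scales = _coef_prior_scales(self.p, priors, self.scales)
        if self.family is Family.beta and len(self.y):
            if np.any(self.y <= 0) or np.any(self.y >= 1):
                raise ValueError("beta outcomes must lie strictly in (0, 1); "
                                 "apply substitute_unit_boundary first")
            self._logy = np.log(self.y)
            self._log1my = np.log1p(-self.y)
        if self.family is Family.negbin and len(self.y):
            if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
                raise ValueError("negbin outcomes must be non-negative integers")
            self.y = np.round(self.y)

    # -- likelihood -------------------------------------------------------

    def _beta_ll(self, eta, phi):
        mu = special.expit(eta)
        if np.any(mu <= 0) or np.any(mu >= 1):
            return -np.inf, None, None
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = np.sum(special.gammaln(phi) - special.gammaln(a)
                    - special.gammaln(b) + (a - 1) * self._logy
                    + (b - 1) * self._log1my)
        dl_dmu = phi * (self._logy - self._log1my
                        - special.digamma(a) + special.digamma(b))
        grad_eta = dl_dmu * mu * (1.0 - mu)
        dl_dphi = np.sum(special.digamma(phi) - mu * special.digamma(a)
                         - (1 - mu) * special.digamma(b)
                         + mu * self._logy + (1 - mu) * self._log1my)
        return float(ll), grad_eta, float(dl_dphi)

    def _negbin_ll(self, eta, phi):
        eta = np.clip(eta, -500, 500)
        mu = np.exp(eta)
        y = self.y
        ll = np.sum(special.gammaln(y + phi) - special.gammaln(phi)
                    - special.gammaln(y + 1)
                    + phi * (math.log(phi) - np.log(phi + mu))
                    + y * (eta - np.log(phi + mu)))
        grad_eta = phi * (y - mu) / (phi + mu)
        dl_dphi = np.sum(special.digamma(y + phi) - special.digamma(phi)
                         + math.log(phi) - np.log(phi + mu)
                         + 1.0 - (y + phi) / (phi + mu))
        return float(ll), grad_eta, float(dl_dphi)

    # -- posterior --------------------------------------------------------

    def value_and_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        beta = theta[: self.p]
        log_phi = theta[self.p]
        if abs(log_phi) > 150:   # exp under/overflow -> zero posterior mass
            return -np.inf, np.zeros(self.dim)
        phi = math.exp(log_phi)
        grad = np.zeros(self.dim)
        total = 0.0
        if len(self.y):
            eta = self.X @ beta
            if self.family is Family.beta:
                ll, grad_eta, dl_dphi = self._beta_ll(eta, phi)
            else:
                ll, grad_eta, dl_dphi = self._negbin_ll(eta, phi)
            if not np.isfinite(ll):
                return -np.inf, np.zeros(self.dim)
            total += ll
            grad[: self.p] += self.X.T @ grad_eta
            grad[self.p] += dl_dphi * phi
        # priors (on the scaled coefficients; includes the constant Jacobian)
        lpc, gc = _normal_vec_lp_grad(beta, self._coef_scales)
        total += lpc
        grad[: self.p] += gc
        lph, gph = _half_t_lp_grad(phi, self.priors.dispersion_df,
                                   self.priors.dispersion_scale)
        total += lph + log_phi          # Jacobian of phi = exp(log_phi)
        grad[self.p] += gph * phi + 1.0
        if not np.isfinite(total):
            return -np.inf, np.zeros(self.dim)
        return float(total), grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered start: slopes near zero, the intercept centred on the
        link-transformed outcome mean so count models start at a finite,
        moderate-gradient point."""
        theta = np.zeros(self.dim)
        theta[: self.p] = 0.1 * rng.standard_normal(self.p)
        if len(self.y):
            ybar = float(np.mean(self.y))
            if self.family is Family.negbin:
                theta[0] += math.log(max(ybar, 0.5))
            else:
                mu0 = min(max(ybar, 0.01), 0.99)
                theta[0] += math.log(mu0 / (1.0 - mu0))
        med = _half_t_median(self.priors.dispersion_df,
                             self.priors.dispersion_scale)
        theta[self.p] = math.log(med) + 0.1 * rng.standard_normal()
        return theta

    def constrain(self, thetas: np.ndarray) -> Dict[str, np.ndarray]:
        """Map raw draws (..., dim) to named constrained-scale draws."""
        out = {name: thetas[..., j] / self.scales[j]
               for j, name in enumerate(self.design.names)}
        out["phi"] = np.exp(thetas[..., self.p])
        return out

    def parameter_vector(self, theta: np.ndarray) -> ParameterVector:
        return ParameterVector(coefficients=theta[: self.p] / self.scales,
                               dispersion=float(math.exp(theta[self.p])))


class SeasonalLogPosterior:
    """Log-normal month-factor + penalized-spline posterior (visits model)."""

    def __init__(self, design: DesignMatrix, y: np.ndarray, priors: PriorSet,
                 basis: np.ndarray):
        self.design = design
        self.y = np.asarray(y, dtype=float)
        if len(self.y) and np.any(self.y <= 0):
            raise ValueError("seasonal outcomes must be strictly positive")
        self.logy = np.log(self.y) if len(self.y) else self.y
        self.B = np.asarray(basis, dtype=float)
        if len(self.y) and self.B.shape[0] != self.y.shape[0]:
            raise ValueError("basis rows must match length of y")
        self.priors = priors
        self.p = design.p
        self.K = self.B.shape[1]
        self.dim = self.p + self.K + 2
        self.names = (list(design.names) + [f"s_{j+1}" for j in range(self.K)]
                      + ["sigma", "spline_sd"])
        self.scales = _column_scales(design.X)
        self.X = design.X / self.scales
        self._coef_scales = _coef_prior_scales(self.p, priors, self.scales)

    def value_and_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        p, K = self.p, self.K
        beta = theta[:p]
        z = theta[p: p + K]
        log_sigma = theta[p + K]
        log_tau = theta[p + K + 1]
        if abs(log_sigma) > 150 or abs(log_tau) > 150:
            return -np.inf, np.zeros(self.dim)
        sigma = math.exp(log_sigma)
        tau = math.exp(log_tau)
        grad = np.zeros(self.dim)
        total = 0.0
        if len(self.y):
            n = len(self.y)
            mu = self.X @ beta + self.B @ (tau * z)
            r = self.logy - mu
            sig2 = sigma * sigma
            total += float(-n * log_sigma - 0.5 * np.sum(r * r) / sig2
                           - 0.5 * n * _LOG2PI)
            dmu = r / sig2
            grad[:p] += self.X.T @ dmu
            Btd = self.B.T @ dmu
            grad[p: p + K] += tau * Btd
            grad[p + K] += -n + float(np.sum(r * r)) / sig2
            grad[p + K + 1] += tau * float(z @ Btd)
        # priors (coefficients on the scaled parameterization)
        lpc, gc = _normal_vec_lp_grad(beta, self._coef_scales)
        lpz, gz = _normal_lp_grad(z, 1.0)
        total += lpc + lpz
        grad[:p] += gc
        grad[p: p + K] += gz
        lpsig, gsig = _half_t_lp_grad(sigma, self.priors.dispersion_df,
                                      self.priors.dispersion_scale)
        total += lpsig + log_sigma
        grad[p + K] += gsig * sigma + 1.0
        lptau, gtau = _half_t_lp_grad(tau, self.priors.dispersion_df,
                                      self.priors.spline_sd_scale)
        total += lptau + log_tau
        grad[p + K + 1] += gtau * tau + 1.0
        if not np.isfinite(total):
            return -np.inf, np.zeros(self.dim)
        return float(total), grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.dim)
        theta[: self.p] = 0.1 * rng.standard_normal(self.p)
        if len(self.y):
            theta[0] = float(np.mean(self.logy)) + 0.1 * rng.standard_normal()
        theta[self.p: self.p + self.K] = 0.1 * rng.standard_normal(self.K)
        med_sig = _half_t_median(self.priors.dispersion_df,
                                 self.priors.dispersion_scale)
        med_tau = _half_t_median(self.priors.dispersion_df,
                                 self.priors.spline_sd_scale)
        theta[self.p + self.K] = math.log(med_sig) + 0.1 * rng.standard_normal()
        theta[self.p + self.K + 1] = math.log(med_tau) + 0.1 * rng.standard_normal()
        return theta

    def constrain(self, thetas: np.ndarray) -> Dict[str, np.ndarray]:
        out = {name: thetas[..., j] / self.scales[j]
               for j, name in enumerate(self.design.names)}
        tau = np.exp(thetas[..., self.p + self.K + 1])
        for j in range(self.K):
            out[f"s_{j+1}"] = tau * thetas[..., self.p + j]
        out["sigma"] = np.exp(thetas[..., self.p + self.K])
        out["spline_sd"] = tau
        return out

    def parameter_vector(self, theta: np.ndarray) -> ParameterVector:
        tau = float(math.exp(theta[self.p + self.K + 1]))
        return ParameterVector(
            coefficients=theta[: self.p] / self.scales,
            dispersion=float(math.exp(theta[self.p + self.K])),
            spline_coeffs=tau * theta[self.p: self.p + self.K],
            spline_sd=tau,
        )


def build_log_posterior(spec: ModelSpec, design: DesignMatrix, y,
                        basis: np.ndarray | None = None):
    """Construct the family-appropriate log posterior for a model spec."""
    y = np.asarray(y, dtype=float)
    if spec.family is Family.seasonal_trend:
        if basis is None:
            raise ValueError("seasonal_trend requires a spline basis")
        return SeasonalLogPosterior(design, y, spec.priors, basis)
    return GlmLogPosterior(spec.family, design, y, spec.priors)
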