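import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from countercast import (DesignMatrix, ModelSpec, ParameterVector, PriorSet,
                         SplineBasis, beta_loglik,
                         beta_shapes_from_mean_precision, build_import_design,
                         build_month_design, build_search_design,
                         exclude_zero_dominated, log_prior, negbin_loglik,
                         seasonal_trend_loglik, spline_basis)
from countercast.panel import Frequency, OutcomeKind, TimeSeriesPanel


def make_panel(refs, kind=OutcomeKind.proportion, focal=None):
    n = len(next(iter(refs.values())))
    times = [dt.date(2015, 1, 1) + dt.timedelta(weeks=i) for i in range(n)]
    if focal is None:
        focal = np.full(n, 0.5) if kind is OutcomeKind.proportion \
            else np.full(n, 5.0)
    return TimeSeriesPanel(times, focal, refs, Frequency.weekly, kind)


class TestBetaShapes:
    @pytest.mark.parametrize("mu,phi,p,q", [
        (0.5, 4.0, 2.0, 2.0),
        (0.25, 8.0, 2.0, 6.0),
    ])
    def test_conversion(self, mu, phi, p, q):
        assert beta_shapes_from_mean_precision(mu, phi) == (p, q)

    @given(st.floats(0.01, 0.99), st.floats(0.1, 100.0))
    def test_round_trip(self, mu, phi):
        p, q = beta_shapes_from_mean_precision(mu, phi)
        assert p + q == pytest.approx(phi)
        assert p / (p + q) == pytest.approx(mu)

    @pytest.mark.parametrize("mu,phi", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0)])
    def test_boundaries_rejected(self, mu, phi):
        with pytest.raises(ValueError):
            beta_shapes_from_mean_precision(mu, phi)


class TestBetaLoglik:
    def test_uniform_is_flat(self):
        # shapes (1, 1): the density is 1 everywhere inside (0, 1)
        assert beta_loglik([0.5], [0.5], 2.0) == pytest.approx(0.0)
        assert beta_loglik([0.3], [0.5], 2.0) == pytest.approx(0.0)

    def test_symmetric_beta33(self):
        # Beta(3,3) density at 1/2 is 1.875
        assert beta_loglik([0.5], [0.5], 6.0) == pytest.approx(math.log(1.875))

    def test_boundary_rejected_with_pointer(self):
        with pytest.raises(ValueError, match="substitute_unit_boundary"):
            beta_loglik([1.0], [0.5], 2.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.05, 0.95, 20)
        mu = rng.uniform(0.2, 0.8, 20)
        perm = rng.permutation(20)
        assert beta_loglik(y, mu, 5.0) == pytest.approx(
            beta_loglik(y[perm], mu[perm], 5.0))


class TestNegbinLoglik:
    def test_pmf_at_zero(self):
        # NB2 pmf at 0 is (phi/(phi+mu))^phi = 1/2 for mu = phi = 1
        assert negbin_loglik([0], [1.0], 1.0) == pytest.approx(math.log(0.5))

    def test_poisson_limit(self):
        want = stats.poisson.logpmf(3, 3.0)
        assert negbin_loglik([3], [3.0], 1e6) == pytest.approx(want, abs=1e-4)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            negbin_loglik([1.5], [2.0], 1.0)
        with pytest.raises(ValueError):
            negbin_loglik([-1], [2.0], 1.0)

    def test_moments_match_nb2(self):
        """Sample mean/variance of draws match (mu, mu + mu^2/phi)."""
        mu, phi, n = 10.0, 5.0, 100_000
        rng = np.random.default_rng(42)
        draws = rng.negative_binomial(phi, phi / (phi + mu), size=n)
        var = mu + mu**2 / phi
        # 3 Monte-Carlo standard errors
        se_mean = math.sqrt(var / n)
        assert draws.mean() == pytest.approx(mu, abs=3 * se_mean)
        assert draws.var(ddof=1) == pytest.approx(var, rel=0.05)


class TestSeasonalLoglik:
    def test_zero_residuals(self):
        n, c = 5, 1.3
        params = ParameterVector(coefficients=np.r_[c, np.zeros(11)],
                                 dispersion=1.0,
                                 spline_coeffs=np.zeros(4), spline_sd=1.0)
        y = np.full(n, math.exp(c))
        ll = seasonal_trend_loglik(y, np.ones(n, int), np.zeros(n), params,
                                   np.zeros((n, 4)))
        assert ll == pytest.approx(n * math.log(1 / math.sqrt(2 * math.pi)))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        n = 8
        months = rng.integers(1, 13, n)
        basis = rng.normal(size=(n, 4))
        y = np.exp(rng.normal(1.0, 0.3, n))
        p1 = ParameterVector(np.r_[0.7, rng.normal(0, 0.2, 11)], 0.5,
                             rng.normal(0, 0.1, 4), 1.0)
        shift = 0.37
        p2 = ParameterVector(np.r_[p1.coefficients[0] + shift,
                                   p1.coefficients[1:]], 0.5,
                             p1.spline_coeffs, 1.0)
        ll1 = seasonal_trend_loglik(y, months, np.zeros(n), p1, basis)
        ll2 = seasonal_trend_loglik(np.exp(np.log(y) + shift), months,
                                    np.zeros(n), p2, basis)
        assert ll1 == pytest.approx(ll2)

    def test_small_case_against_direct_sum(self):
        y = np.array([2.0, 3.0, 4.0])
        months = np.array([1, 2, 1])
        coefs = np.r_[0.9, 0.2, np.zeros(10)]
        params = ParameterVector(coefs, 0.4, np.array([0.1, -0.1]), 1.0)
        basis = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        mu = np.array([0.9 + 0.1, 0.9 + 0.2 - 0.1, 0.9 + 0.0])
        want = sum(stats.norm.logpdf(np.log(yi), m, 0.4)
                   for yi, m in zip(y, mu))
        got = seasonal_trend_loglik(y, months, np.zeros(3), params, basis)
        assert got == pytest.approx(want)

    def test_nonpositive_rejected(self):
        params = ParameterVector(np.zeros(12), 1.0)
        with pytest.raises(ValueError):
            seasonal_trend_loglik([0.0], [1], [0.0], params, np.zeros((1, 0)))


class TestDesigns:
    @pytest.mark.parametrize("k,cols", [(6, 22), (1, 2), (3, 7)])
    def test_search_design_column_count(self, k, cols):
        refs = {f"r{j}": np.full(30, 0.5) for j in range(k)}
        d = build_search_design(make_panel(refs))
        assert d.p == cols == 1 + k + k * (k - 1) // 2
        assert d.names[0] == "intercept"

    def test_search_interactions_are_products(self):
        refs = {f"r{j}": np.full(10, 0.5) for j in range(3)}
        d = build_search_design(make_panel(refs))
        for name in d.names[4:]:
            assert ":" in name
            col = d.X[:, d.names.index(name)]
            np.testing.assert_allclose(col, 0.25)

    def test_search_requires_references(self):
        empty = make_panel({"r": np.full(5, 0.5)}).with_references({})
        with pytest.raises(ValueError):
            build_search_design(empty)

    @pytest.mark.parametrize("k,cols", [(4, 5), (2, 3)])
    def test_import_design_main_effects_only(self, k, cols):
        refs = {f"r{j}": np.full(24, 3.0) for j in range(k)}
        d = build_import_design(make_panel(refs, OutcomeKind.count))
        assert d.p == cols
        assert d.names == tuple(["intercept"] + [f"r{j}" for j in range(k)])

    def test_month_design_january_base(self):
        dates = [dt.date(2016, m, 1) for m in range(1, 13)]
        d = build_month_design(dates)
        assert d.p == 12
        # January row: intercept only
        np.testing.assert_array_equal(d.X[0], np.r_[1.0, np.zeros(11)])
        # every other month has exactly one dummy set
        assert np.all(d.X[1:, 1:].sum(axis=1) == 1)


class TestZeroDominated:
    def make_count_panel(self, cols):
        return make_panel(cols, OutcomeKind.count)

    def test_dominated_column_dropped(self):
        zeros = np.zeros(24); zeros[:4] = 5
        keep = np.full(24, 7.0)
        panel = self.make_count_panel({"dead": zeros, "alive": keep})
        out = exclude_zero_dominated(panel, threshold=0.5)
        assert out.reference_names == ("alive",)

    def test_no_zeros_retained(self):
        panel = self.make_count_panel({"alive": np.full(24, 7.0)})
        assert exclude_zero_dominated(panel).reference_names == ("alive",)

    def test_threshold_one_keeps_everything(self):
        panel = self.make_count_panel({"dead": np.zeros(24)})
        assert exclude_zero_dominated(panel, 1.0).reference_names == ("dead",)

    def test_all_dropped_rejected(self):
        panel = self.make_count_panel({"dead": np.zeros(24)})
        with pytest.raises(ValueError):
            exclude_zero_dominated(panel, threshold=0.5)


class TestSplineBasis:
    def test_partition_of_unity(self):
        t = np.linspace(-0.6, 0.6, 80)
        sb = SplineBasis(t, num_basis=10)
        np.testing.assert_allclose(sb.raw(t).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_coefficients_contribute_nothing(self):
        t = np.linspace(0, 1, 30)
        B, _ = spline_basis(t, 8)
        assert B.shape == (30, 6)
        np.testing.assert_allclose(B @ np.zeros(B.shape[1]), 0.0)

    def test_random_part_orthogonal_to_fixed(self):
        t = np.linspace(-0.5, 0.5, 60)
        B, _ = spline_basis(t, 10)
        F = np.column_stack([np.ones_like(t), t])
        np.testing.assert_allclose(F.T @ B, 0.0, atol=1e-9)

    def test_quadratic_recovery(self):
        """Least squares on intercept + trend + basis reproduces a quadratic."""
        t = np.linspace(-0.5, 0.5, 100)
        target = 1.0 + 0.8 * t - 2.0 * t**2
        B, _ = spline_basis(t, 10)
        X = np.column_stack([np.ones_like(t), t, B])
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        fitted = X @ coef
        rng_range = target.max() - target.min()
        assert np.max(np.abs(fitted - target)) < 0.01 * rng_range

    def test_linear_extension_beyond_range(self):
        t = np.linspace(0, 1, 50)
        sb = SplineBasis(t, 8)
        coefs = np.random.default_rng(0).normal(size=8)
        # values at 1.1 and 1.2 continue on the boundary tangent
        f = lambda x: sb.raw(np.array(x)) @ coefs
        v11, v12 = f([1.1])[0], f([1.2])[0]
        slope = (v12 - v11) / 0.1
        v10 = f([1.0 - 1e-9])[0]
        assert v11 == pytest.approx(v10 + slope * 0.1, rel=1e-4, abs=1e-6)

    def test_too_few_basis_rejected(self):
        with pytest.raises(ValueError):
            spline_basis(np.linspace(0, 1, 10), 3)


class TestLogPrior:
    def test_matches_density_oracle(self):
        priors = PriorSet()
        params = ParameterVector(np.zeros(3), 25.0)
        want = (stats.norm.logpdf(0, 0, 10) + 2 * stats.norm.logpdf(0, 0, 2)
                + math.log(2) + stats.t.logpdf(25.0, 3, scale=25))
        assert log_prior(params, priors) == pytest.approx(want)

    def test_gaussian_quadratic_in_slope(self):
        priors = PriorSet()
        base = ParameterVector(np.array([0.0, 0.0]), 1.0)
        moved = ParameterVector(np.array([0.0, 2.0]), 1.0)
        assert log_prior(base, priors) - log_prior(moved, priors) \
            == pytest.approx(0.5)

    def test_nonpositive_dispersion_is_minus_inf(self):
        assert log_prior(ParameterVector(np.zeros(2), 0.0), PriorSet()) \
            == -math.inf

    def test_spline_block(self):
        priors = PriorSet(dispersion_scale=2.0)
        params = ParameterVector(np.zeros(2), 1.0,
                                 spline_coeffs=np.array([0.5]), spline_sd=1.5)
        want = (stats.norm.logpdf(0, 0, 10) + stats.norm.logpdf(0, 0, 2)
                + math.log(2) + stats.t.logpdf(1.0, 3, scale=2)
                + math.log(2) + stats.t.logpdf(1.5, 3, scale=2)
                + stats.norm.logpdf(0.5, 0, 1.5))
        assert log_prior(params, priors) == pytest.approx(want)


class TestModelSpec:
    def test_family_defaults(self):
        assert ModelSpec.for_family("beta").priors.dispersion_scale == 25.0
        assert ModelSpec.for_family("negbin").priors.dispersion_scale == 25.0
        assert ModelSpec.for_family("seasonal_trend").priors.dispersion_scale == 2.0

    def test_dict_round_trip(self):
        spec = ModelSpec.for_family("seasonal_trend", num_basis=12)
        assert ModelSpec.from_dict(spec.to_dict()) == spec
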