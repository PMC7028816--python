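import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from countercast import (DesignMatrix, ModelSpec, PosteriorSamples,
                         SamplerConfig, ScenarioConfig, effect_ratio,
                         evaluate_impact, exceedance_probability, generate,
                         posterior_predict, prepare_study)
from countercast.impact import SUMMARY_COLUMNS


class TestEffectRatio:
    def test_small_example(self):
        out = effect_ratio(2.0, [1.0, 2.0, 4.0])
        # ratio draws are {2, 1, 0.5}; their median is 1
        assert out.median == pytest.approx(1.0)

    def test_identity(self):
        out = effect_ratio(3.0, np.full(100, 3.0))
        assert out.median == 1.0
        assert out.ci50 == (1.0, 1.0)
        assert out.ci90 == (1.0, 1.0)

    def test_quantiles_match_direct_recomputation(self):
        rng = np.random.default_rng(0)
        draws = rng.negative_binomial(2, 2 / 7.0, size=4000).astype(float)
        observed = 10.0
        out = effect_ratio(observed, draws)
        ratios = observed / draws[draws != 0]
        lo90, lo50, med, hi50, hi90 = np.quantile(
            ratios, [0.05, 0.25, 0.5, 0.75, 0.95])
        assert out.median == pytest.approx(med)
        assert out.ci50 == pytest.approx((lo50, hi50))
        assert out.ci90 == pytest.approx((lo90, hi90))
        assert out.n_zero_dropped == int((draws == 0).sum())

    def test_all_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            effect_ratio(1.0, np.zeros(10))

    @given(st.floats(0.1, 100), st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(3.0, 2.0, size=200)
        obs = float(rng.gamma(3.0, 2.0))
        a = effect_ratio(obs, draws)
        b = effect_ratio(obs * c, draws * c)
        assert a.median == pytest.approx(b.median)
        assert a.ci90 == pytest.approx(b.ci90)
        assert exceedance_probability(obs, draws) == \
            exceedance_probability(obs * c, draws * c)


class TestExceedanceProbability:
    def test_observed_above_all(self):
        assert exceedance_probability(10.0, [1, 2, 3]) == 1.0

    def test_at_empirical_median(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(10001)
        med = float(np.median(draws))
        assert exceedance_probability(med, draws) == pytest.approx(0.5, abs=0.01)

    def test_mid_probability_tie_rule(self):
        assert exceedance_probability(2.0, [2, 2, 4, 4]) == 0.25

    @given(st.lists(st.floats(0, 10), min_size=5, max_size=50),
           st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_observed(self, draws, a, b):
        lo, hi = min(a, b), max(a, b)
        assert exceedance_probability(lo, draws) <= \
            exceedance_probability(hi, draws)


def make_degenerate_samples(values: dict, chains=4, kept=50):
    """PosteriorSamples concentrated at one parameter point."""
    cfg = SamplerConfig(iterations=2 * kept, chains=chains)
    draws = {k: np.full((chains, kept), v) for k, v in values.items()}
    return PosteriorSamples(draws=draws, parameter_names=tuple(values),
                            config=cfg)


class TestPosteriorPredict:
    def test_beta_degenerate_concentrates_at_inverse_link(self):
        X = np.column_stack([np.ones(3), [0.2, 0.5, 0.8]])
        design = DesignMatrix(names=("intercept", "x"), X=X)
        samples = make_degenerate_samples(
            {"intercept": -1.0, "x": 2.0, "phi": 1e7})
        pred = posterior_predict(samples, ModelSpec.for_family("beta"),
                                 design, rng_seed=0)
        want = expit(X @ np.array([-1.0, 2.0]))
        np.testing.assert_allclose(pred.draws.mean(axis=0), want, atol=2e-3)
        assert pred.draws.std(axis=0).max() < 2e-3

    def test_negbin_predictive_mean_matches_expectation(self):
        """Law of total expectation: predictive mean ~= mean of exp(X beta)."""
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(2), [0.1, 0.4]])
        design = DesignMatrix(names=("intercept", "x"), X=X)
        cfg = SamplerConfig(iterations=2000, chains=4)
        b0 = rng.normal(2.0, 0.05, (4, 1000))
        b1 = rng.normal(1.0, 0.05, (4, 1000))
        phi = np.full((4, 1000), 20.0)
        samples = PosteriorSamples(
            draws={"intercept": b0, "x": b1, "phi": phi},
            parameter_names=("intercept", "x", "phi"), config=cfg)
        pred = posterior_predict(samples, ModelSpec.for_family("negbin"),
                                 design, rng_seed=3)
        mu = np.exp(samples.flat_matrix(design.names) @ X.T)
        want = mu.mean(axis=0)
        got = pred.draws.mean(axis=0)
        se = pred.draws.std(axis=0) / np.sqrt(pred.n_draws)
        np.testing.assert_array_less(np.abs(got - want), 5 * se + 0.05 * want)
        assert np.all(pred.draws >= 0)
        np.testing.assert_allclose(pred.draws, np.round(pred.draws))

    def test_seeded_reproducibility(self):
        X = np.ones((2, 1))
        design = DesignMatrix(names=("intercept",), X=X)
        samples = make_degenerate_samples({"intercept": 0.0, "phi": 10.0})
        spec = ModelSpec.for_family("beta")
        a = posterior_predict(samples, spec, design, rng_seed=7)
        b = posterior_predict(samples, spec, design, rng_seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_column_mismatch_rejected(self):
        design = DesignMatrix(names=("intercept", "missing"),
                              X=np.ones((2, 2)))
        samples = make_degenerate_samples({"intercept": 0.0, "phi": 10.0})
        with pytest.raises(ValueError, match="missing"):
            posterior_predict(samples, ModelSpec.for_family("beta"), design,
                              rng_seed=0)


@pytest.fixture(scope="module")
def import_result():
    cfg = ScenarioConfig.imports(seed=3)
    study, truth = generate(cfg)
    spec = ModelSpec.for_family("negbin")
    return evaluate_impact(study, spec, SamplerConfig(iterations=600, seed=1))


class TestEvaluateImpact:
    def test_summary_shape_and_columns(self, import_result):
        summary = import_result.summary
        assert list(summary.columns) == list(SUMMARY_COLUMNS)
        assert len(summary) == 6      # post periods of the default scenario

    def test_interval_nesting_invariant(self, import_result):
        s = import_result.summary
        assert (s["ratio_lo90"] <= s["ratio_lo50"]).all()
        assert (s["ratio_lo50"] <= s["ratio_median"]).all()
        assert (s["ratio_median"] <= s["ratio_hi50"]).all()
        assert (s["ratio_hi50"] <= s["ratio_hi90"]).all()
        assert s["p_exceed"].between(0, 1).all()

    def test_pre_bands_cover_most_observations(self, import_result):
        bands = import_result.pre_bands
        frac = ((bands["observed"] >= bands["lo90"])
                & (bands["observed"] <= bands["hi90"])).mean()
        assert frac > 0.6

    def test_short_pre_period_refused(self):
        """Fitting is refused when the pre-period has fewer than twice the
        design-matrix columns."""
        import datetime as dt
        from countercast import InterventionStudy, TimeSeriesPanel
        rng = np.random.default_rng(0)
        n, k = 30, 6          # 6 refs -> 22 columns -> needs 44 pre rows
        times = [dt.date(2016, 1, 3) + dt.timedelta(weeks=i) for i in range(n)]
        panel = TimeSeriesPanel(
            times, rng.uniform(0.05, 0.9, n),
            {f"r{j}": rng.uniform(0.05, 0.9, n) for j in range(k)},
            "weekly", "proportion")
        study = InterventionStudy(panel, times[20])
        with pytest.raises(ValueError, match="pre-period"):
            prepare_study(study, ModelSpec.for_family("beta"))

    def test_family_kind_mismatch(self):
        cfg = ScenarioConfig.imports(seed=3)
        study, _ = generate(cfg)
        with pytest.raises(TypeError, match="outcome_kind"):
            evaluate_impact(study, ModelSpec.for_family("beta"),
                            SamplerConfig(iterations=100, seed=0))

    def test_decoy_references_are_dropped(self):
        cfg = ScenarioConfig.imports(seed=5, n_decoys=2)
        study, _ = generate(cfg)
        prepared = prepare_study(study, ModelSpec.for_family("negbin"))
        assert set(prepared.dropped_references) == {"decoy_1", "decoy_2"}
        assert not any(n.startswith("decoy")
                       for n in prepared.design_pre.names)

    def test_search_preprocessing_substitutes_boundary(self):
        cfg = ScenarioConfig.search(n_periods=120, k_references=3,
                                    intervention_index=104, seed=2)
        study, _ = generate(cfg)
        prepared = prepare_study(study, ModelSpec.for_family("beta"))
        allvals = np.concatenate([prepared.y_pre, prepared.y_post])
        assert allvals.max() == pytest.approx(0.99)
        assert prepared.n_boundary_substitutions == 1
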