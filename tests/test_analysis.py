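"""Trace statistics, Welch test, and the recursive area estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinesim import (
    AreaEstimator, EstimatorParams, ModelParams, area_statistics,
    delta_area_regression, fit_area_estimator, predict_area, welch_test,
)
from spinesim.simulator import SimulationTrace


def make_trace(area, n_f=None, dt=0.125, lifetimes=()):
    area = np.asarray(area, float)
    if n_f is None:
        n_f = np.zeros(len(area), dtype=int)
    log = pd.DataFrame({
        "id": range(len(lifetimes)),
        "birth": 0.0,
        "death": lifetimes,
        "lifetime": lifetimes,
        "x_n": 0.0, "y_n": 0.0,
    })
    return SimulationTrace(
        t=np.arange(len(area)) * dt, area=area,
        n_f=np.asarray(n_f), mean_b=np.full(len(area), np.nan),
        focus_log=log, snapshots=[], a_s=float(area.min() or 1.0),
        params=ModelParams(dt=dt))


def recursion_oracle(params: EstimatorParams, n_f):
    """Literal step-by-step evaluation of the area recursion (oracle)."""
    out = np.empty(len(n_f))
    out[0] = params.a0
    for j in range(1, len(n_f)):
        out[j] = (out[j - 1] - params.phi * (out[j - 1] - params.a_s)
                  + params.m * n_f[j] + params.b)
    return out


class TestAreaStatistics:
    def test_constant_series(self):
        stats = area_statistics(make_trace(np.full(100, 2.5)))
        assert stats.mean_area == 2.5
        assert stats.sd_area == 0.0
        assert stats.bootstrap_sd == 0.0
        assert list(stats.acf) == [1.0]

    def test_white_noise_acf_is_negligible(self):
        rng = np.random.default_rng(0)
        n = 10_000
        stats = area_statistics(make_trace(rng.normal(1.0, 0.1, n)),
                                rng=np.random.default_rng(1))
        assert stats.acf[0] == pytest.approx(1.0)
        # per-lag 3/sqrt(n) white-noise band on the leading lags
        assert np.abs(stats.acf[1:21]).max() < 3.0 / np.sqrt(n)
        # across all lags, essentially everything stays inside the band
        assert np.mean(np.abs(stats.acf[1:]) < 3.0 / np.sqrt(n)) > 0.98

    def test_acf_normalized_and_bounded(self):
        rng = np.random.default_rng(2)
        # strongly autocorrelated series (random walk, then detrended)
        series = np.cumsum(rng.normal(0, 1, 3000))
        stats = area_statistics(make_trace(series), rng=rng)
        assert stats.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(stats.acf) <= 1.0 + 1e-12)

    def test_bootstrap_sd_tracks_standard_error(self):
        rng = np.random.default_rng(3)
        n = 5000
        stats = area_statistics(make_trace(rng.normal(0.7, 0.05, n)),
                                n_boot=200, rng=np.random.default_rng(4))
        assert stats.bootstrap_sd == pytest.approx(0.05 / np.sqrt(n),
                                                   rel=0.35)

    def test_mean_lifetime_from_log(self):
        stats = area_statistics(make_trace(np.ones(10) + np.arange(10) * 0.1,
                                           lifetimes=[2.0, 4.0]))
        assert stats.mean_lifetime == pytest.approx(3.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            area_statistics(make_trace([1.0]))


class TestWelchTest:
    def test_identical_samples(self):
        t, p = welch_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        # textbook Welch formula evaluated by hand for these samples
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected_t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        t, p = welch_test(a, b)
        assert t == pytest.approx(expected_t, abs=1e-10)
        from scipy.stats import t as t_dist
        dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert p == pytest.approx(2 * t_dist.sf(abs(expected_t), dof),
                                  abs=1e-10)

    def test_antisymmetric_in_sample_order(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        t1, p1 = welch_test(a, b)
        t2, p2 = welch_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_test([1.0], [2.0, 3.0])


class TestPredictArea:
    def test_frozen_parameters_constant_series(self):
        est = EstimatorParams(m=0.0, b=0.0, phi=0.0, a0=0.8, a_s=0.5)
        pred, rmse = predict_area(est, np.zeros(50))
        assert np.allclose(pred, 0.8)
        assert rmse is None

    def test_geometric_decay_toward_resting_area(self):
        est = EstimatorParams(m=0.1, b=0.0, phi=0.01, a0=1.0, a_s=0.5)
        pred, _ = predict_area(est, np.zeros(200))
        expected = 0.5 + (1.0 - 0.5) * (1 - 0.01) ** np.arange(200)
        assert np.allclose(pred, expected)

    def test_matches_stepwise_recursion_oracle(self):
        rng = np.random.default_rng(6)
        n_f = rng.integers(0, 5, 300)
        est = EstimatorParams(m=0.003, b=-0.0004, phi=0.0027, a0=0.75,
                              a_s=0.5)
        pred, _ = predict_area(est, n_f)
        assert np.allclose(pred, recursion_oracle(est, n_f), atol=1e-12)

    def test_empty_series_rejected(self):
        est = EstimatorParams(m=0.0, b=0.0, phi=0.1, a0=1.0, a_s=0.5)
        with pytest.raises(ValueError):
            predict_area(est, [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(-0.01, 0.01),
           st.floats(0.0, 0.01), st.integers(0, 6))
    def test_bounded_for_contractive_decay(self, phi, b, m, nf_max):
        """With phi in (0,1) and bounded focus counts the recursion cannot
        diverge: it is a contraction toward a finite fixed band."""
        rng = np.random.default_rng(7)
        n_f = rng.integers(0, nf_max + 1, 500)
        est = EstimatorParams(m=m, b=b, phi=phi, a0=0.75, a_s=0.5)
        pred, _ = predict_area(est, n_f)
        bound = (abs(est.a0) + est.a_s
                 + (abs(m) * nf_max + abs(b) + phi * est.a_s) / phi)
        assert np.all(np.abs(pred) <= bound + 1.0)


class TestFitAreaEstimator:
    def make_synthetic(self, seed, noise, n=4000):
        rng = np.random.default_rng(seed)
        truth = EstimatorParams(m=0.0027, b=-0.0004, phi=0.003, a0=0.75,
                                a_s=0.5)
        # persistent integer focus counts, like the simulator produces
        n_f = np.clip(np.round(2 + np.cumsum(rng.normal(0, 0.15, n))), 0, 8)
        area = recursion_oracle(truth, n_f) + rng.normal(0, noise, n)
        return truth, n_f, area

    def test_noise_free_fit_is_exact(self):
        truth, n_f, area = self.make_synthetic(8, noise=0.0)
        est, rmse = fit_area_estimator(area, n_f, truth.a_s)
        assert rmse < 1e-10
        assert est.m == pytest.approx(truth.m, rel=1e-6)
        assert est.phi == pytest.approx(truth.phi, rel=1e-6)
        assert est.b == pytest.approx(truth.b, rel=1e-6)
        assert est.a0 == pytest.approx(truth.a0, rel=1e-6)

    def test_parameter_recovery_under_small_noise(self):
        truth, n_f, area = self.make_synthetic(9, noise=1e-4)
        est, _ = fit_area_estimator(area, n_f, truth.a_s)
        assert est.m == pytest.approx(truth.m, rel=0.05)
        assert est.phi == pytest.approx(truth.phi, rel=0.05)
        assert est.a0 == pytest.approx(truth.a0, rel=0.05)

    def test_estimates_converge_as_noise_vanishes(self):
        errors = []
        for noise in (3e-3, 3e-4, 3e-5):
            truth, n_f, area = self.make_synthetic(10, noise=noise)
            est, _ = fit_area_estimator(area, n_f, truth.a_s)
            errors.append(abs(est.m - truth.m) + abs(est.phi - truth.phi))
        assert errors[0] > errors[1] > errors[2]

    def test_train_window_restricts_the_fit(self):
        truth, n_f, area = self.make_synthetic(11, noise=0.0)
        area = area.copy()
        area[3000:] += 10.0  # corrupt everything past the window
        est, rmse = fit_area_estimator(area, n_f, truth.a_s, (0, 3000))
        assert rmse < 1e-10
        assert est.m == pytest.approx(truth.m, rel=1e-6)

    def test_invalid_window_rejected(self):
        truth, n_f, area = self.make_synthetic(12, noise=0.0)
        with pytest.raises(ValueError):
            fit_area_estimator(area, n_f, truth.a_s, (100, 50))


class TestAreaEstimatorModelAPI:
    def test_fit_predict_summary(self):
        rng = np.random.default_rng(13)
        truth = EstimatorParams(m=0.002, b=0.0, phi=0.005, a0=0.7, a_s=0.5)
        n_f = rng.integers(0, 4, 2000)
        area = recursion_oracle(truth, n_f) + rng.normal(0, 1e-5, 2000)
        model = AreaEstimator(area, n_f, truth.a_s)
        res = model.fit()
        assert res.params.m == pytest.approx(truth.m, rel=0.05)
        pred, rmse = res.predict(reference=area)
        assert rmse == pytest.approx(res.rmse, rel=0.2)
        text = res.summary()
        assert "training RMSE" in text and "A_s" in text

    def test_delta_area_regression_recovers_slope(self):
        truth = EstimatorParams(m=0.002, b=-0.0005, phi=0.0, a0=0.7, a_s=0.5)
        rng = np.random.default_rng(14)
        n_f = rng.integers(0, 4, 3000)
        area = recursion_oracle(truth, n_f)
        fit = delta_area_regression(area, n_f)
        # with phi = 0 the per-step change is exactly m * n_f + b
        assert fit.slope == pytest.approx(truth.m, rel=1e-9)
        assert fit.intercept == pytest.approx(truth.b, rel=1e-6)
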