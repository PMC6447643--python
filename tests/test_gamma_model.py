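import numpy as np
import pytest

from fpaperf.errors import (
    DegenerateCurveError,
    DegenerateRegressorError,
    IllPosedLandmarkError,
    InsufficientDataError,
)
from fpaperf.gamma_model import (
    GammaParams,
    fit_gamma,
    gamma_curve,
    gamma_value_and_derivatives,
    landmark_fraction,
    timing_landmarks,
    timing_regression,
)
from fpaperf.synthetic import AorticCurve


def brute_force_d2_argmax(params: GammaParams, n: int = 1_000_000) -> float:
    """Oracle: maximize the second finite difference of the curve values."""
    h = 1e-4
    t = np.linspace(params.t0 + 1e-6, params.t0 + params.tau, n)
    f = lambda x: gamma_curve(x, params.A, params.tau, params.b, params.C, params.t0)
    d2 = (f(t + h) - 2.0 * f(t) + f(t - h)) / h**2
    return float(t[np.argmax(d2)])


class TestValueAndDerivatives:
    def test_peak_value_and_stationarity(self, exact_params):
        p = exact_params
        val, d1, _ = gamma_value_and_derivatives(p, p.t0 + p.tau)
        assert val == pytest.approx(p.A + p.C, rel=1e-12)
        assert d1 == pytest.approx(0.0, abs=1e-9)

    def test_baseline_before_arrival(self, exact_params):
        val, d1, d2 = gamma_value_and_derivatives(exact_params, 2.0)
        assert (val, d1, d2) == (exact_params.C, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = GammaParams(
            A=rng.uniform(100, 800), tau=rng.uniform(5, 20),
            b=rng.uniform(2.2, 12), C=rng.uniform(0, 80), t0=rng.uniform(0, 10),
        )
        t = p.t0 + np.linspace(0.3, 2.5, 17) * p.tau
        f = lambda x: gamma_curve(x, p.A, p.tau, p.b, p.C, p.t0)
        h = 1e-4
        d1_fd = (f(t + h) - f(t - h)) / (2 * h)
        h2 = 1e-3  # larger step: curb float cancellation in the d2 stencil
        d2_fd = (f(t + h2) - 2 * f(t) + f(t - h2)) / h2**2
        _, d1, d2 = gamma_value_and_derivatives(p, t)
        scale1 = np.max(np.abs(d1_fd)) + 1e-12
        scale2 = np.max(np.abs(d2_fd)) + 1e-12
        assert np.all(np.abs(d1 - d1_fd) / scale1 < 1e-6)
        assert np.all(np.abs(d2 - d2_fd) / scale2 < 1e-6)


class TestTimingLandmarks:
    def test_peak_closed_form(self):
        res = timing_landmarks(GammaParams(A=123.0, tau=10.0, b=3.0))
        assert res.t_peak == pytest.approx(10.0, abs=1e-12)

    def test_amplitude_and_baseline_invariance(self):
        a = timing_landmarks(GammaParams(A=100.0, tau=9.0, b=4.0, C=0.0))
        b = timing_landmarks(GammaParams(A=200.0, tau=9.0, b=4.0, C=55.0))
        assert a.t_base == pytest.approx(b.t_base, abs=1e-7)
        assert a.T_g == pytest.approx(b.T_g, abs=1e-7)

    def test_against_brute_force_grid(self):
        p = GammaParams(A=500.0, tau=10.0, b=3.0)
        res = timing_landmarks(p)
        oracle = brute_force_d2_argmax(p)
        assert res.t_base == pytest.approx(oracle, abs=1e-3)
        assert res.T_g == pytest.approx(p.tau - (oracle - p.t0), abs=1e-3)

    def test_shift_invariance(self):
        a = timing_landmarks(GammaParams(A=100.0, tau=8.0, b=5.0, t0=0.0))
        b = timing_landmarks(GammaParams(A=100.0, tau=8.0, b=5.0, t0=4.2))
        assert b.t_base == pytest.approx(a.t_base + 4.2, abs=1e-7)
        assert b.T_g == pytest.approx(a.T_g, abs=1e-7)

    @pytest.mark.parametrize("b", [2.3, 3.0, 5.0, 10.0])
    @pytest.mark.parametrize("k", [0.5, 2.0, 7.5])
    def test_tau_linearity(self, b, k):
        base = timing_landmarks(GammaParams(A=1.0, tau=1.0, b=b))
        scaled = timing_landmarks(GammaParams(A=1.0, tau=k, b=b))
        assert scaled.T_g == pytest.approx(k * base.T_g, rel=1e-6)

    def test_ill_posed_for_small_b(self):
        with pytest.raises(IllPosedLandmarkError):
            timing_landmarks(GammaParams(A=1.0, tau=5.0, b=2.0))

    def test_landmark_fraction_consistent(self):
        frac = landmark_fraction(3.0)
        res = timing_landmarks(GammaParams(A=1.0, tau=13.0, b=3.0))
        assert res.t_base == pytest.approx(13.0 * frac, rel=1e-6)


class TestFitGamma:
    def test_exact_recovery(self, exact_params):
        p = exact_params
        t = np.arange(0.0, 40.0, 0.7)
        curve = AorticCurve(
            times=t, enhancement=gamma_curve(t, p.A, p.tau, p.b, p.C, p.t0)
        )
        fit = fit_gamma(curve)
        for name in ("A", "tau", "b", "C", "t0"):
            assert getattr(fit, name) == pytest.approx(
                getattr(p, name), rel=1e-4, abs=1e-4
            )
        assert fit.fit_rss < 1e-8

    def test_noisy_tau_recovery(self, exact_params):
        # Monte-Carlo calibration: median |tau error| under 10-HU noise
        p = exact_params
        t = np.arange(0.0, 40.0, 0.7)
        clean = gamma_curve(t, p.A, p.tau, p.b, p.C, p.t0)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            curve = AorticCurve(times=t, enhancement=clean + rng.normal(0, 10, t.size))
            fit = fit_gamma(curve)
            errors.append(abs(fit.tau - p.tau))
        assert np.median(errors) < 0.5

    def test_constant_curve_degenerate(self):
        t = np.arange(0.0, 20.0, 1.0)
        with pytest.raises(DegenerateCurveError):
            fit_gamma(AorticCurve(times=t, enhancement=np.full(t.size, 42.0)))

    def test_too_few_samples(self):
        t = np.arange(5.0)
        with pytest.raises(InsufficientDataError):
            fit_gamma(AorticCurve(times=t, enhancement=t * 10))

    def test_landmark_pipeline_idempotent(self, noiseless_curve):
        fit1 = fit_gamma(noiseless_curve)
        marks1 = timing_landmarks(fit1)
        resampled = AorticCurve(
            times=noiseless_curve.times,
            enhancement=gamma_curve(
                noiseless_curve.times, fit1.A, fit1.tau, fit1.b, fit1.C, fit1.t0
            ),
        )
        marks2 = timing_landmarks(fit_gamma(resampled))
        assert marks2.T_g == pytest.approx(marks1.T_g, abs=1e-3)


class TestTimingRegression:
    def test_exact_linear_points(self):
        x = np.array([3.0, 5.0, 7.0, 9.0])
        pairs = list(zip(x, x + 2.3))
        res = timing_regression(pairs)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(2.3, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        # identity-line residuals are the constant offset 2.3
        assert res.rmse == pytest.approx(2.3, abs=1e-10)

    def test_grouping_averages_before_regression(self):
        pairs = [(3.0, 5.0), (3.0, 7.0), (5.0, 8.0), (7.0, 10.0)]
        res = timing_regression(pairs, groups=["a", "a", "b", "c"])
        # subject a collapses to (3, 6): exact line y = x + 3
        assert res.n == 3
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(3.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            timing_regression([(1.0, 2.0), (2.0, 3.0)])

    def test_constant_regressor(self):
        with pytest.raises(DegenerateRegressorError):
            timing_regression([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])

    def test_literal_rms_flag(self):
        rng = np.random.default_rng(0)
        x = np.linspace(2, 10, 12)
        y = x + 2.3 + rng.normal(0, 0.5, x.size)
        conventional = timing_regression(list(zip(x, y)))
        literal = timing_regression(list(zip(x, y)), literal_rms=True)
        resid = y - x
        assert literal.rmse == pytest.approx(np.sqrt(np.std(resid, ddof=1)), rel=1e-12)
        assert conventional.rmse == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-12)
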