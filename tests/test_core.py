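"""Parabola-regression engine: closed forms, error signal, window sizing."""
import numpy as np
import pytest

from ecgparafit import (
    EcgSignal,
    error_profile,
    fit_parabola_window,
    pqrst_window_halfwidth,
    r_window_halfwidth,
)


def _lstsq_oracle(y, w):
    """Generic two-parameter least squares on the (i-j)^2 regressor."""
    d = np.arange(-w, w + 1)
    X = np.column_stack([d.astype(float) ** 2, np.ones(2 * w + 1)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1], float(np.mean(resid**2))


def _sig(y, fs=500.0):
    return EcgSignal(samples=np.asarray(y, float), fs=fs)


class TestFitParabolaWindow:
    def test_exact_parabola_recovered(self):
        d = np.arange(-5, 6)
        y = np.concatenate([2.0 * d**2 + 3.0, [0.0]])
        fit = fit_parabola_window(_sig(y), center=5, w=5)
        assert fit.a == pytest.approx(2.0, abs=1e-12)
        assert fit.v == pytest.approx(3.0, abs=1e-12)
        assert fit.epsilon == pytest.approx(0.0, abs=1e-12)

    def test_constant_signal(self):
        fit = fit_parabola_window(_sig(np.full(21, 1.7)), center=10, w=4)
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.v == pytest.approx(1.7, abs=1e-12)
        assert fit.epsilon == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_uncorrelated_with_symmetric_regressor(self):
        # odd part of the window is orthogonal to (i-j)^2
        d = np.arange(-6, 7)
        y = np.concatenate([0.4 * d + 1.5, [0.0]])
        fit = fit_parabola_window(_sig(y), center=6, w=6)
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.v == pytest.approx(1.5, abs=1e-12)
        assert fit.epsilon > 0

    @pytest.mark.parametrize("w", [1, 3, 7, 15])
    def test_matches_generic_least_squares(self, rng, w):
        for _ in range(50):
            y = rng.normal(size=2 * w + 1)
            fit = fit_parabola_window(_sig(np.concatenate([y, [0.0]])), center=w, w=w)
            a, v, eps = _lstsq_oracle(y, w)
            assert fit.a == pytest.approx(a, rel=1e-9, abs=1e-12)
            assert fit.v == pytest.approx(v, rel=1e-9, abs=1e-12)
            assert fit.epsilon == pytest.approx(eps, rel=1e-9, abs=1e-12)

    def test_epsilon_is_mean_squared_residual(self, rng):
        y = rng.normal(size=31)
        fit = fit_parabola_window(_sig(np.concatenate([y, [0.0]])), center=15, w=15)
        d = np.arange(-15, 16).astype(float)
        resid = y - (fit.a * d**2 + fit.v)
        assert fit.epsilon == pytest.approx(float(np.mean(resid**2)), abs=1e-12)

    def test_least_squares_optimality_under_perturbation(self, rng):
        y = rng.normal(size=21)
        sig = _sig(np.concatenate([y, [0.0]]))
        fit = fit_parabola_window(sig, center=10, w=10)
        d = np.arange(-10, 11).astype(float)

        def eps_at(a, v):
            return float(np.mean((y - (a * d**2 + v)) ** 2))

        for da in (-1e-4, 1e-4):
            for dv in (-1e-4, 0.0, 1e-4):
                assert eps_at(fit.a + da, fit.v + dv) >= fit.epsilon - 1e-15

    def test_bounds_checked(self):
        sig = _sig(np.zeros(20))
        with pytest.raises(ValueError):
            fit_parabola_window(sig, center=2, w=5)
        with pytest.raises(ValueError):
            fit_parabola_window(sig, center=10, w=0)
        with pytest.raises(ValueError):
            fit_parabola_window(sig, center=10, w=10)


class TestErrorProfile:
    def test_pure_parabola_vertex_has_zero_error(self):
        d = np.arange(-50, 51).astype(float)
        sig = _sig(-0.01 * d**2 + 1.0)
        prof = error_profile(sig, w=8)
        k = np.argmin(prof.epsilon)
        assert prof.centers[k] == 50
        assert prof.epsilon[k] == pytest.approx(0.0, abs=1e-12)
        assert prof.a[k] == pytest.approx(-0.01, abs=1e-9)

    def test_gaussian_apex_at_error_minimum(self, gaussian_peak):
        # near-flat tails also fit a degenerate parabola with eps ~ 0, so
        # the apex is singled out among centers with non-negligible |a|
        sig, apex = gaussian_peak
        prof = error_profile(sig, w=6)
        curved = np.abs(prof.a) > 1e-4
        k = np.flatnonzero(curved)[np.argmin(prof.epsilon[curved])]
        assert abs(prof.centers[k] - apex) <= 1

    def test_vectorized_matches_scalar_path(self, rng):
        sig = _sig(rng.normal(size=200))
        w = 7
        prof = error_profile(sig, w)
        assert len(prof) == 200 - 2 * w
        for k in [0, 1, 50, 185]:
            fit = fit_parabola_window(sig, int(prof.centers[k]), w)
            assert prof.a[k] == pytest.approx(fit.a, abs=1e-12)
            assert prof.v[k] == pytest.approx(fit.v, abs=1e-12)
            assert prof.epsilon[k] == pytest.approx(fit.epsilon, abs=1e-12)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            error_profile(_sig(np.zeros(10)), w=5)


class TestWindowSizing:
    @pytest.mark.parametrize(
        "fn,fs,expected_w",
        [
            (r_window_halfwidth, 500, 15),
            (r_window_halfwidth, 360, 11),
            (pqrst_window_halfwidth, 500, 6),
            (pqrst_window_halfwidth, 250, 3),
        ],
    )
    def test_halfwidth_rounding(self, fn, fs, expected_w):
        assert fn(fs) == expected_w

    def test_window_lengths_at_500_hz(self):
        assert 2 * r_window_halfwidth(500) + 1 == 31
        assert 2 * pqrst_window_halfwidth(500) + 1 == 13

    def test_floor_at_one(self):
        assert r_window_halfwidth(1) == 1
        assert pqrst_window_halfwidth(1) == 1

    def test_positive_fs_required(self):
        with pytest.raises(ValueError):
            r_window_halfwidth(0)
        with pytest.raises(ValueError):
            pqrst_window_halfwidth(-500)
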