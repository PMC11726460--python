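"""Cosine fitting, season windows, amplitudes and the crown-height clock."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from palaeofeed.seasonal_model import (
    SeasonalModel,
    cold_season_windows,
    dentine_age_months,
    enamel_age_months,
    fit_cosine,
    percent_crown_height,
    predict_cosine,
    tooth_amplitude,
)

TRUE = dict(A=2.0, X=30.0, x0=10.0, M=-6.0)


def cosine(x, A, X, x0, M):
    return A * np.cos(2 * np.pi * (np.asarray(x) - x0) / X) + M


def circ_err(a, b, period):
    d = abs(a - b) % period
    return min(d, period - d)


def grid_oracle(x, y, X_grid, x0_step=0.05):
    """Independent dense grid search over (X, x0), linear solve for (A, M)."""
    best = (np.inf, None)
    x = np.asarray(x)
    y = np.asarray(y)
    for X in X_grid:
        for x0 in np.arange(0.0, X, x0_step):
            c = np.cos(2 * np.pi * (x - x0) / X)
            design = np.column_stack([c, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((y - design @ coef) ** 2))
            if rss < best[0]:
                best = (rss, (coef[0], X, x0, coef[1]))
    return best


class TestFitCosine:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 30, 10)
        model = fit_cosine(x, cosine(x, **TRUE))
        assert model.A == pytest.approx(2.0, abs=1e-6)
        assert model.X == pytest.approx(30.0, abs=1e-5)
        assert model.x0 == pytest.approx(10.0, abs=1e-5)
        assert model.M == pytest.approx(-6.0, abs=1e-6)
        assert model.rmse < 1e-6

    def test_noisy_recovery_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 33, 12)
        y = cosine(x, **TRUE) + rng.normal(0, 0.3, 12)
        model = fit_cosine(x, y, crown_height=33.0)
        rss_oracle, params = grid_oracle(x, y, np.arange(10, 99, 0.5), x0_step=0.2)
        assert model.rmse ** 2 * 12 <= rss_oracle + 1e-9
        assert abs(model.A - TRUE["A"]) <= 0.3
        assert abs(model.X - TRUE["X"]) <= 3.0
        assert circ_err(model.x0, TRUE["x0"], model.X) <= 2.0
        assert abs(model.M - TRUE["M"]) <= 0.2

    def test_constant_series_not_identifiable(self):
        x = np.linspace(0, 30, 8)
        with pytest.raises(ValueError, match="not identifiable"):
            fit_cosine(x, np.full(8, -6.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_cosine([0, 10, 20, 30], [-6, -7, -6, -5])

    def test_narrow_span_rejected(self):
        x = np.linspace(20, 25, 8)
        with pytest.raises(ValueError, match="span"):
            fit_cosine(x, cosine(x, **TRUE), crown_height=45.0)

    def test_scale_equivariance(self):
        x = np.linspace(0, 30, 12)
        y = cosine(x, **TRUE)
        m1 = fit_cosine(x, y)
        m2 = fit_cosine(3.0 * x, y)
        assert m2.X == pytest.approx(3.0 * m1.X, rel=1e-4)
        assert m2.x0 == pytest.approx(3.0 * m1.x0, rel=1e-3, abs=1e-3)
        assert m2.A == pytest.approx(m1.A, abs=1e-6)
        assert m2.M == pytest.approx(m1.M, abs=1e-6)

    def test_refit_on_own_predictions_is_idempotent(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 40, 13)
        y = cosine(x, 1.5, 32.0, 5.0, -7.0) + rng.normal(0, 0.3, 13)
        m1 = fit_cosine(x, y, crown_height=40.0)
        m2 = fit_cosine(x, predict_cosine(m1, x), crown_height=40.0)
        assert m2.A == pytest.approx(m1.A, abs=1e-8)
        assert m2.X == pytest.approx(m1.X, abs=1e-6)
        assert circ_err(m2.x0, m1.x0, m1.X) <= 1e-6
        assert m2.M == pytest.approx(m1.M, abs=1e-8)


class TestPredict:
    MODEL = SeasonalModel("t", **TRUE, rmse=0.0, n_points=10)

    @pytest.mark.parametrize("x, expected", [
        (10.0, -4.0),          # maximum: M + A
        (25.0, -8.0),          # half period later: M - A
        (40.0, -4.0),          # full period: M + A again
    ])
    def test_landmarks(self, x, expected):
        assert predict_cosine(self.MODEL, x) == pytest.approx(expected, abs=1e-12)


class TestColdWindows:
    MODEL = SeasonalModel("t", **TRUE, rmse=0.0, n_points=10)

    def test_single_cycle_window_matches_root_find(self):
        windows = cold_season_windows(self.MODEL, (0.0, 30.0))
        cold = [w for w in windows if w.label == "cold"]
        assert len(cold) == 1
        (w,) = cold
        # independent oracle: solve predicted(x) = M - A/2 numerically
        f = lambda x: predict_cosine(self.MODEL, x) - (TRUE["M"] - TRUE["A"] / 2)
        left = brentq(f, 10.0, 25.0)
        right = brentq(f, 25.0, 30.0 + 1e-6)  # root sits at the interval end
        assert w.start_pos == pytest.approx(left, abs=1e-9)
        assert w.end_pos == pytest.approx(right, abs=1e-9)
        assert (w.start_pos + w.end_pos) / 2 == pytest.approx(25.0, abs=1e-9)
        assert w.end_pos - w.start_pos == pytest.approx(10.0, abs=1e-9)

    def test_interval_inside_warm_phase(self):
        windows = cold_season_windows(self.MODEL, (5.0, 15.0))
        assert all(w.label == "warm" for w in windows)

    def test_two_cycles_two_cold_windows(self):
        windows = cold_season_windows(self.MODEL, (0.0, 60.0))
        assert sum(w.label == "cold" for w in windows) == 2

    def test_windows_tile_interval_without_overlap(self):
        windows = cold_season_windows(self.MODEL, (3.0, 57.0))
        assert windows[0].start_pos == 3.0 and windows[-1].end_pos == 57.0
        for a, b in zip(windows, windows[1:]):
            assert a.end_pos == pytest.approx(b.start_pos, abs=1e-12)


class TestAmplitude:
    def test_max_minus_min(self):
        assert tooth_amplitude([-11, -12, -10.5]) == pytest.approx(1.5)

    def test_constant_is_zero(self):
        assert tooth_amplitude([-11.0] * 4) == 0.0

    def test_fewer_than_two_values(self):
        with pytest.raises(ValueError, match=">= 2"):
            tooth_amplitude([-11.0])

    @settings(max_examples=100, derandomize=True)
    @given(vals=st.lists(st.floats(-20, 0), min_size=2, max_size=12),
           shift=st.floats(-5, 5))
    def test_translation_invariant_and_nonnegative(self, vals, shift):
        a = tooth_amplitude(vals)
        assert a >= 0
        assert tooth_amplitude([v + shift for v in vals]) == pytest.approx(a, abs=1e-9)


class TestCrownClock:
    @pytest.mark.parametrize("pos, ch, pct", [(22.5, 45, 50), (0, 45, 0), (45, 45, 100)])
    def test_percent_crown_height(self, pos, ch, pct):
        assert percent_crown_height(pos, ch) == pytest.approx(pct)

    def test_position_beyond_crown_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            percent_crown_height(46, 45)

    @pytest.mark.parametrize("frac, dentine, enamel", [
        (1.0, 6, 12), (0.0, 18, 24), (0.5, 12, 18),
    ])
    def test_age_maps(self, frac, dentine, enamel):
        assert dentine_age_months(frac) == pytest.approx(dentine)
        assert enamel_age_months(frac) == pytest.approx(enamel)

    def test_out_of_range_fraction(self):
        with pytest.raises(ValueError, match="outside"):
            dentine_age_months(1.2)

    @settings(max_examples=100, derandomize=True)
    @given(frac=st.floats(0, 1))
    def test_enamel_lags_dentine_by_six_months_everywhere(self, frac):
        assert enamel_age_months(frac) - dentine_age_months(frac) == pytest.approx(
            6.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(f1=st.floats(0, 1), f2=st.floats(0, 1))
    def test_age_maps_strictly_decreasing(self, f1, f2):
        if f1 + 1e-9 < f2:  # separated beyond float rounding of the affine map
            assert dentine_age_months(f1) > dentine_age_months(f2)
            assert enamel_age_months(f1) > enamel_age_months(f2)


class TestParameterRecovery:
    def test_recovery_over_synthetic_teeth(self):
        """Median recovery error over 40 noisy teeth within stated bounds."""
        rng = np.random.default_rng(2024)
        ex, e0 = [], []
        for _ in range(40):
            A = rng.uniform(1, 4)
            X = rng.uniform(25, 40)
            x0 = rng.uniform(0, X)
            M = rng.uniform(-8, -4)
            n = int(rng.integers(10, 15))
            ch = 45.0
            x = np.linspace(0.1 * ch, 0.98 * ch, n)
            y = cosine(x, A, X, x0, M) + rng.normal(0, 0.3, n)
            m = fit_cosine(x, y, crown_height=ch)
            ex.append(abs(m.X - X))
            e0.append(circ_err(m.x0, x0, X))
        assert np.median(ex) <= 2.0
        assert np.median(e0) <= 1.5
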