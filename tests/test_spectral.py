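"""Lomb-Scargle periodogram, false-alarm testing and band classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import lombscargle

from bearrhythms import spectral

from conftest import tone_window


def brute_force_power(t, y, periods):
    """Independent oracle: least-squares sinusoid fit at each frequency."""
    yc = y - y.mean()
    s2 = yc @ yc / (len(y) - 1)
    out = np.empty(len(periods))
    for i, p in enumerate(periods):
        w = 2 * np.pi / p
        X = np.column_stack([np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        out[i] = yc @ (X @ beta) / (2 * s2)
    return out


class TestPeriodGrid:
    def test_frequency_step_is_reciprocal_window_length(self):
        periods, _ = spectral.build_period_grid(600.0, oversampling=1)
        freqs = 1.0 / periods
        steps = np.diff(freqs)
        assert np.allclose(steps, 1.0 / 600.0)

    def test_oversampling_multiplies_grid_density(self):
        p1, m1 = spectral.build_period_grid(600.0, oversampling=1)
        p4, m4 = spectral.build_period_grid(600.0, oversampling=4)
        # 4x density up to the bracketing points at the band edges
        assert abs(len(p4) / len(p1) - 4.0) < 0.02
        assert m1 == m4  # M counts the un-oversampled band grid

    def test_endpoints_bracket_band(self):
        periods, _ = spectral.build_period_grid(600.0, oversampling=4)
        assert periods.max() >= 168.0 and periods.min() <= 2.0
        assert np.all(np.diff(periods) < 0)  # descending

    def test_short_window_shrinks_max_period_with_warning(self):
        with pytest.warns(UserWarning, match="shrinking"):
            periods, _ = spectral.build_period_grid(200.0)
        assert periods.max() <= 200.0


class TestLombScarglePower:
    def test_pure_tone_peak_location_and_height(self):
        w = tone_window(period_hours=24.0, amplitude=1.0, noise_sd=0.0, cadence_minutes=5)
        pg = spectral.periodogram(w.hours_since_start, w.values)
        n = len(w)
        assert abs(1 / pg.peak_period_hours - 1 / 24.0) <= 1.0 / (4 * 600.0)
        # a pure tone concentrates ~ N/2 of the normalized power at its peak
        assert 0.9 * n / 2 <= pg.peak_power <= 1.02 * n / 2

    def test_matches_brute_force_on_uneven_design(self, rng):
        t = np.sort(rng.uniform(0, 600, 200))
        y = np.sin(2 * np.pi * t / 24) + rng.normal(0, 1, 200)
        periods = np.linspace(2.5, 150, 50)
        ours = spectral.lomb_scargle_power(t, y, periods)
        oracle = brute_force_power(t, y, periods)
        assert np.max(np.abs(ours - oracle) / oracle) < 1e-8

    def test_matches_scipy_implementation(self, rng):
        t = np.sort(rng.uniform(0, 600, 300))
        y = rng.normal(0, 1, 300)
        periods = np.linspace(3, 160, 80)
        ours = spectral.lomb_scargle_power(t, y, periods)
        yc = y - y.mean()
        s2 = yc @ yc / (len(y) - 1)
        ref = lombscargle(t, yc, 2 * np.pi / periods, normalize=False) / s2
        assert np.max(np.abs(ours - ref) / ref) < 1e-6

    def test_batch_equals_loop(self, rng):
        t = np.sort(rng.uniform(0, 600, 120))
        Y = rng.normal(0, 1, (5, 120))
        periods = np.linspace(3, 150, 40)
        batch = spectral.lomb_scargle_power_batch(t, Y, periods)
        for i in range(5):
            single = spectral.lomb_scargle_power(t, Y[i], periods)
            assert np.allclose(batch[i], single, rtol=1e-12)

    def test_invariance_to_value_offset_and_time_shift(self, rng):
        t = np.sort(rng.uniform(0, 600, 150))
        y = np.sin(2 * np.pi * t / 30) + rng.normal(0, 0.5, 150)
        periods = np.linspace(3, 150, 40)
        base = spectral.lomb_scargle_power(t, y, periods)
        assert np.allclose(spectral.lomb_scargle_power(t, y + 123.4, periods), base, atol=1e-10)
        assert np.allclose(spectral.lomb_scargle_power(t + 77.7, y, periods), base, atol=1e-8)

    def test_white_noise_powers_approximately_exponential(self, rng):
        # pooled single-frequency powers under the null vs Exponential(1)
        t = np.sort(rng.uniform(0, 600, 100))
        Y = rng.normal(0, 1, (1000, 100))
        pw = spectral.lomb_scargle_power_batch(t, Y, np.array([24.0, 11.0, 53.0])).ravel()
        qs = np.quantile(pw, [0.25, 0.5, 0.75, 0.9])
        expected = -np.log1p(-np.array([0.25, 0.5, 0.75, 0.9]))
        assert np.allclose(qs, expected, rtol=0.15)

    def test_constant_series_rejected(self):
        t = np.arange(20.0)
        with pytest.raises(ValueError, match="variance"):
            spectral.lomb_scargle_power(t, np.full(20, 5.0), np.array([5.0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            spectral.lomb_scargle_power(np.arange(5.0), np.arange(5.0), np.array([5.0]))


class TestFalseAlarm:
    def test_zero_power_is_certain_false_alarm(self):
        assert spectral.false_alarm_probability(0.0, 298) == 1.0

    def test_single_frequency_algebra(self):
        assert spectral.false_alarm_probability(np.log(20.0), 1) == pytest.approx(0.05)

    def test_monotone_decreasing_in_power(self):
        z = np.linspace(0, 30, 100)
        p = spectral.false_alarm_probability(z, 298)
        assert np.all(np.diff(p) <= 0)

    def test_baluev_bounds_independent_formula_from_above(self):
        t = np.arange(1200) * 0.5
        z = np.linspace(5, 20, 30)
        pb = spectral.false_alarm_probability_baluev(z, t)
        pi = spectral.false_alarm_probability(z, 298)
        assert np.all(pb >= pi * 0.999)


class TestClassification:
    @pytest.mark.parametrize(
        "period,p,expected",
        [
            (24.0, 0.001, "diel"),
            (12.0, 0.001, "ultradian"),
            (120.0, 0.001, "infradian"),
            (17.99, 0.001, "ultradian"),
            (18.0, 0.001, "diel"),  # half-open boundary
            (35.99, 0.001, "diel"),
            (36.0, 0.001, "infradian"),
            (24.0, 0.5, "arrhythmic"),  # insignificant peak
        ],
    )
    def test_band_boundaries(self, period, p, expected):
        assert spectral.classify_period(period, p, alpha=0.01) == expected

    @given(
        period=st.floats(2.0, 168.0),
        p=st.floats(0.0, 1.0),
        alpha=st.sampled_from([0.01, 0.05]),
    )
    def test_pure_function_of_peak_and_significance(self, period, p, alpha):
        cls = spectral.classify_period(period, p, alpha)
        if p > alpha:
            assert cls == "arrhythmic"
        elif period < 18.0:
            assert cls == "ultradian"
        elif period < 36.0:
            assert cls == "diel"
        else:
            assert cls == "infradian"

    def test_significant_tone_windows(self):
        for period, expected in [(24.0, "diel"), (12.0, "ultradian"), (120.0, "infradian")]:
            w = tone_window(period_hours=period, amplitude=1.0, noise_sd=0.3, seed=int(period))
            call = spectral.classify_window(w)
            assert call.rhythm_class == expected
            assert call.p_value <= 0.01

    def test_reports_peak_period_even_when_arrhythmic(self, rng):
        w = tone_window(period_hours=24.0, amplitude=0.0, noise_sd=1.0, seed=5, cadence_minutes=60)
        call = spectral.classify_window(w)
        assert call.peak_period_hours > 0
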