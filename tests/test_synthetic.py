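"""Ground-truth guarantees of the synthetic bear-year generator."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bearrhythms import segmentation as seg
from bearrhythms.synthetic import (
    DEFAULT_VARIABLE_PARAMS,
    SimulationConfig,
    VariableParams,
    simulate_bear_year,
    simulate_rhythm_cohort,
    simulate_weather,
)


def noise_free_params():
    return {
        var: dataclasses.replace(p, diel_amplitude=0.0, ultradian_amplitude=0.0,
                                 infradian_amplitude=0.0, noise_sd=0.0, hib_diel_amplitude=0.0)
        for var, p in DEFAULT_VARIABLE_PARAMS.items()
    }


class TestBearYear:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_bears=1, seed=7)
        a, _ = simulate_bear_year(cfg, "b1", variables=("tb", "activity"))
        b, _ = simulate_bear_year(cfg, "b1", variables=("tb", "activity"))
        for var in ("tb", "activity"):
            assert np.array_equal(a[var].values, b[var].values)
            assert a[var].timestamps.equals(b[var].timestamps)

    def test_activity_is_integer_within_sensor_range(self):
        cfg = SimulationConfig(n_bears=1, seed=1)
        s, _ = simulate_bear_year(cfg, "b1", variables=("activity",))
        v = s["activity"].values
        assert np.all(v == np.rint(v))
        assert v.min() >= 0 and v.max() <= 510

    def test_timestamps_strictly_increasing_with_planted_gap(self):
        capture = dt.date(2015, 7, 10)
        cfg = SimulationConfig(n_bears=1, seed=1, capture_dates=(capture,))
        s, _ = simulate_bear_year(cfg, "b1", variables=("tb",))
        ts = s["tb"].timestamps
        assert (np.diff(ts.asi8) > 0).all()
        lo = pd.Timestamp(capture, tz=ts.tz)
        hi = lo + pd.Timedelta(days=14)
        assert not (((ts >= lo) & (ts < hi)).any())

    def test_noise_free_daily_means_equal_state_means(self):
        cfg = SimulationConfig(
            n_bears=1, seed=0, variable_params=noise_free_params(), den_date_jitter_days=0
        )
        s, truth = simulate_bear_year(cfg, "b1", variables=("tb",))
        daily = seg.daily_means(s["tb"])
        by_date = daily.set_index("date")["mean"]
        p = cfg.variable_params["tb"]
        # deep in the active state and the hibernation core
        assert by_date[dt.date(2015, 6, 15)] == pytest.approx(p.active_mean, abs=1e-9)
        assert by_date[dt.date(2016, 1, 15)] == pytest.approx(p.hib_mean, abs=1e-9)
        # threshold anchoring on the den dates themselves
        assert by_date[truth.den_entry] == pytest.approx(36.4, abs=1e-9)
        assert by_date[truth.den_exit] == pytest.approx(36.7, abs=1e-9)

    def test_oscillating_trace_keeps_daily_means_on_trajectory(self):
        # diel + ultradian components average to zero over a full day
        cfg = SimulationConfig(n_bears=1, seed=0, den_date_jitter_days=0)
        vp = dict(cfg.variable_params)
        vp["tb"] = dataclasses.replace(vp["tb"], noise_sd=0.0)
        cfg = dataclasses.replace(cfg, variable_params=vp)
        s, _ = simulate_bear_year(cfg, "b1", variables=("tb",))
        daily = seg.daily_means(s["tb"]).set_index("date")["mean"]
        assert daily[dt.date(2015, 7, 1)] == pytest.approx(37.3, abs=1e-9)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="60 days"):
            SimulationConfig(
                start_date=dt.date(2015, 5, 1),
                end_date=dt.date(2015, 6, 1),
                den_entry_day=None,
                den_exit_day=None,
            )

    def test_entry_after_exit_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            SimulationConfig(
                den_entry_day=dt.date(2016, 4, 1), den_exit_day=dt.date(2015, 11, 1)
            )


class TestWeather:
    def test_deterministic_table(self):
        a = simulate_weather(dt.date(2015, 5, 1), dt.date(2016, 5, 1), seed=3)
        b = simulate_weather(dt.date(2015, 5, 1), dt.date(2016, 5, 1), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_summer_snow_is_zero(self):
        w = simulate_weather(dt.date(2015, 6, 1), dt.date(2015, 9, 30), seed=0)
        assert (w["snow_depth"] == 0.0).all()

    def test_values_within_study_area_ranges(self):
        w = simulate_weather(dt.date(2015, 1, 1), dt.date(2016, 12, 31), seed=2)
        assert w["ta_mean"].between(-15.4, 19.1).all()
        assert w["snow_depth"].between(0.0, 0.63).all()
        assert (w.groupby("station_id")["snow_depth"].max() > 0.1).all()

    def test_needs_three_stations(self):
        with pytest.raises(ValueError, match="3 stations"):
            simulate_weather(dt.date(2015, 5, 1), dt.date(2015, 8, 1), n_stations=2)


class TestRhythmCohort:
    def test_zero_coefficients_give_uniform_classes(self):
        coef = np.zeros((2, 3))
        data, truth = simulate_rhythm_cohort(2000, coef, {"x": (0, 1)}, seed=0)
        freqs = data["rhythm_class"].value_counts(normalize=True)
        se = np.sqrt(0.25 * 0.75 / 2000)
        for cls in ("diel", "ultradian", "infradian", "arrhythmic"):
            assert abs(freqs[cls] - 0.25) < 3 * se
        assert np.allclose(truth.class_probabilities, 0.25)

    def test_large_intercept_saturates(self):
        coef = np.zeros((2, 3))
        # reference class is 'diel'; drive everything away from the others
        coef[0, :] = -10.0
        data, _ = simulate_rhythm_cohort(3000, coef, {"x": (0, 1)}, seed=1)
        assert (data["rhythm_class"] == "diel").mean() >= 0.999

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coefficient matrix"):
            simulate_rhythm_cohort(10, np.zeros((3, 3)), {"x": (0, 1)})

    def test_probabilities_consistent_with_labels(self):
        coef = np.array([[1.0, -1.0, 0.0], [0.5, 0.0, -0.5]])
        data, truth = simulate_rhythm_cohort(5000, coef, {"x": (-2, 2)}, seed=2)
        assert truth.class_probabilities.shape == (5000, 4)
        assert np.allclose(truth.class_probabilities.sum(axis=1), 1.0)
        # empirical frequency of each class tracks the mean generating probability
        classes = ("diel", "ultradian", "infradian", "arrhythmic")
        for j, cls in enumerate(classes):
            emp = (data["rhythm_class"] == cls).mean()
            exp = truth.class_probabilities[:, j].mean()
            assert abs(emp - exp) < 0.025
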