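import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bearrhythms.types import STUDY_TZ, AnalysisWindow, BiologgingSeries

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_series(
    values,
    start="2015-06-01",
    cadence_minutes=30.0,
    bear_id="b1",
    variable="tb",
):
    """Series on a regular grid from explicit values."""
    idx = pd.date_range(
        pd.Timestamp(start, tz=STUDY_TZ),
        periods=len(values),
        freq=pd.Timedelta(minutes=cadence_minutes),
    )
    return BiologgingSeries(bear_id=bear_id, variable=variable, timestamps=idx, values=np.asarray(values, float))


def daily_series(daily_values, start_date=dt.date(2015, 8, 1), samples_per_day=4, bear_id="b1"):
    """Tb series whose daily means equal ``daily_values`` exactly."""
    vals = np.repeat(np.asarray(daily_values, float), samples_per_day)
    return make_series(
        vals, start=start_date.isoformat(), cadence_minutes=1440 / samples_per_day, bear_id=bear_id
    )


def tone_window(
    period_hours=24.0,
    amplitude=1.0,
    noise_sd=0.0,
    days=25,
    cadence_minutes=20.0,
    seed=0,
    state="active",
    variable="tb",
    mean=37.0,
):
    """An AnalysisWindow holding a sinusoid plus white noise."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp("2015-06-01", tz=STUDY_TZ)
    idx = pd.date_range(
        start, start + pd.Timedelta(days=days), freq=pd.Timedelta(minutes=cadence_minutes), inclusive="left"
    )
    hours = (idx.asi8 - start.value) / 3.6e12
    vals = mean + amplitude * np.sin(2 * np.pi * hours / period_hours + rng.uniform(0, 2 * np.pi))
    vals = vals + rng.normal(0, noise_sd, len(idx))
    return AnalysisWindow(
        bear_id="b1",
        variable=variable,
        state=state,
        start=start,
        end=start + pd.Timedelta(days=days),
        timestamps=idx,
        values=vals,
        season=2015,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
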