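"""Double-plot raster matrices and period summary tables.

A double plot (actogram / thermogram / HR raster) bins each day of a
series into time-of-day cells and draws day x on the left and day x+1 on
the right of each row, so phase drift across midnight stays visible.
Sunrise/sunset overlays come from standard solar geometry and agree with
the day-length covariate by construction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import day_length
from .types import BiologgingSeries

MINUTES_PER_DAY = 1440


@dataclass
class DoublePlotMatrix:
    """Day-by-day raster: rows are days, columns two concatenated days."""

    values: np.ndarray  # (n_days, 2 * bins_per_day); NaN = no samples
    row_dates: list[dt.date]
    bin_minutes: int
    sunrise: list[dt.datetime | None] | None = None
    sunset: list[dt.datetime | None] | None = None

    @property
    def bins_per_day(self) -> int:
        return self.values.shape[1] // 2

    def to_frame(self) -> pd.DataFrame:
        cols = [f"min_{b * self.bin_minutes:04d}" for b in range(2 * self.bins_per_day)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "date", self.row_dates)
        return df


def double_plot_matrix(series: BiologgingSeries, bin_minutes: int = 60) -> DoublePlotMatrix:
    """Bin a series by local time of day into a double-plot matrix.

    Cell value is the mean of the samples falling in that bin; bins with
    no samples are NaN (missing, never zero — zero would fabricate
    inactivity).  The right half of row d equals the left half of row d+1
    wherever both exist; the last row's right half is missing.
    """
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    bins_per_day = MINUTES_PER_DAY // bin_minutes
    ts = series.timestamps
    first_day = ts[0].normalize()
    day_idx = ((ts.normalize() - first_day) / pd.Timedelta(days=1)).astype(int).to_numpy()
    minute_of_day = ts.hour * 60 + ts.minute
    bin_idx = (minute_of_day // bin_minutes).to_numpy()

    n_days = int(day_idx.max()) + 1
    sums = np.zeros((n_days, bins_per_day))
    counts = np.zeros((n_days, bins_per_day))
    np.add.at(sums, (day_idx, bin_idx), series.values)
    np.add.at(counts, (day_idx, bin_idx), 1.0)
    with np.errstate(invalid="ignore"):
        single = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)

    right = np.vstack([single[1:], np.full((1, bins_per_day), np.nan)])
    values = np.hstack([single, right])
    row_dates = [(first_day + pd.Timedelta(days=int(d))).date() for d in range(n_days)]
    return DoublePlotMatrix(values=values, row_dates=row_dates, bin_minutes=bin_minutes)


def _equation_of_time_minutes(doy: np.ndarray) -> np.ndarray:
    """Spencer's Fourier fit of the equation of time (minutes)."""
    g = 2.0 * np.pi * (doy - 1) / 365.0
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def sunrise_sunset(
    latitude_deg: float,
    longitude_deg: float,
    date: dt.date,
    tz_offset_hours: float = 1.0,
) -> tuple[dt.datetime | None, dt.datetime | None]:
    """Civil sunrise and sunset instants for one date.

    Solar noon = 12:00 − EoT − longitude/15 + tz offset; sunrise/sunset
    sit half the day length either side, using the same declination model
    as the day-length covariate, so (sunset − sunrise) matches it exactly.
    Polar day/night (day length saturating at 0 or 24 h) returns (None,
    None): there is no crossing to mark.
    """
    dl = day_length(latitude_deg, date)
    if dl <= 0.0 or dl >= 24.0:
        return None, None
    doy = float(pd.Timestamp(date).dayofyear)
    eot_min = float(_equation_of_time_minutes(np.array([doy]))[0])
    noon = 12.0 - eot_min / 60.0 - longitude_deg / 15.0 + tz_offset_hours
    base = dt.datetime.combine(date, dt.time())
    sunrise = base + dt.timedelta(hours=noon - dl / 2.0)
    sunset = base + dt.timedelta(hours=noon + dl / 2.0)
    return sunrise, sunset


def attach_sun_track(
    matrix: DoublePlotMatrix, latitude_deg: float, longitude_deg: float, tz_offset_hours: float = 1.0
) -> DoublePlotMatrix:
    """Add per-row sunrise/sunset instants for overlay plotting."""
    matrix.sunrise = []
    matrix.sunset = []
    for d in matrix.row_dates:
        sr, ss = sunrise_sunset(latitude_deg, longitude_deg, d, tz_offset_hours)
        matrix.sunrise.append(sr)
        matrix.sunset.append(ss)
    return matrix


def period_summary(calls: pd.DataFrame, windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean/min/max peak period per (state, rhythm class) with sample sizes.

    ``calls`` must carry state/bear information (join with the windows
    table first, or pass ``windows`` keyed by window_id to join here).
    Arrhythmic rows keep their non-significant peak period and are flagged
    in the ``nonsignificant`` column (an asterisk in formatted output).
    """
    df = calls.copy()
    if windows is not None:
        df = df.merge(
            windows[["window_id", "state", "bear_id", "variable"]], on="window_id", how="left"
        )
    for col in ("state", "bear_id"):
        if col not in df.columns:
            raise ValueError(f"calls table lacks required column {col!r}")
    keys = ["variable", "state", "rhythm_class"] if "variable" in df.columns else ["state", "rhythm_class"]
    out = (
        df.groupby(keys, sort=True)
        .agg(
            mean_period_h=("peak_period_hours", "mean"),
            min_period_h=("peak_period_hours", "min"),
            max_period_h=("peak_period_hours", "max"),
            n=("peak_period_hours", "size"),
            n_individuals=("bear_id", "nunique"),
        )
        .reset_index()
    )
    out["nonsignificant"] = out["rhythm_class"] == "arrhythmic"
    return out


def format_period_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render periods as strings with the asterisk convention for
    arrhythmic (non-significant) rows."""
    out = summary.copy()
    star = np.where(out["nonsignificant"], "*", "")
    for col in ("mean_period_h", "min_period_h", "max_period_h"):
        out[col] = [f"{v:.1f}{s}" for v, s in zip(out[col], star)]
    return out.drop(columns=["nonsignificant"])
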