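"""Per-window environmental and intrinsic predictors.

Environmental drivers (ambient temperature, snow depth, day length) are
averaged over each analysis window: weather comes from the three nearest
stations by inverse-distance-weighted interpolation, day length from the
standard solar-declination model at the study latitude.  Intrinsic
predictors (sex, age class, reproductive status, body mass, den
attributes) are joined from per-bear metadata.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings

import numpy as np
import pandas as pd

from .types import AnalysisWindow

EARTH_RADIUS_KM = 6371.0088
#: Solar elevation offset (degrees) in the day-length / sunrise model;
#: 0.8333° ~ atmospheric refraction plus the solar half-diameter.
SUN_ANGLE_DEG = 0.8333
DEN_TYPES = ("anthill", "nest", "rock", "soil", "uprooted tree")


def day_length(latitude_deg: float, date: dt.date | np.ndarray) -> float | np.ndarray:
    """Daylight hours from solar declination (Forsythe ecological model).

    theta = 0.2163108 + 2 atan(0.9671396 tan(0.00860 (J - 186)))
    decl  = asin(0.39795 cos(theta))
    D     = 24 - (24/pi) acos[(sin p + sin L sin decl) / (cos L cos decl)]

    with J the day of year, L the latitude and p = 0.8333°.  The argument
    is clamped to [-1, 1] (polar saturation to 0 or 24 h, with a warning).
    """
    scalar = isinstance(date, dt.date)
    dates = pd.DatetimeIndex([date] if scalar else date)
    doy = dates.dayofyear.to_numpy(dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    decl = np.arcsin(0.39795 * np.cos(theta))
    lat = math.radians(latitude_deg)
    a = (math.sin(math.radians(SUN_ANGLE_DEG)) + math.sin(lat) * np.sin(decl)) / (
        math.cos(lat) * np.cos(decl)
    )
    if (np.abs(a) > 1).any():
        warnings.warn("polar day/night: day length clamped to 0 or 24 h", stacklevel=2)
    a = np.clip(a, -1.0, 1.0)
    hours = 24.0 - (24.0 / math.pi) * np.arccos(a)
    return float(hours[0]) if scalar else hours


def day_length_direction(
    start_date: dt.date, end_date: dt.date, latitude_deg: float
) -> str:
    """'increasing' or 'decreasing' day length over [start, end].

    Evaluated endpoint-to-endpoint; an exact tie (e.g. a window symmetric
    about a solstice) is called increasing by convention.
    """
    d0 = day_length(latitude_deg, start_date)
    d1 = day_length(latitude_deg, end_date)
    return "increasing" if d1 >= d0 else "decreasing"


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-friendly)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


WEATHER_VALUE_COLS = ("ta_min", "ta_mean", "ta_max", "snow_depth")


def idw_interpolate(
    stations: pd.DataFrame,
    target_lat: float,
    target_lon: float,
    date: dt.date,
    k: int = 3,
    power: float = 2.0,
) -> dict[str, float]:
    """IDW estimate of the daily weather at a point from the k nearest stations.

    ``stations`` is a long table with columns station_id, lat, lon, date
    and the weather values.  Weights are proportional to distance^-power
    over the k nearest stations holding data on ``date``, normalized to
    sum to one.  If the target coincides with a station (< 1 m) that
    station's values are returned exactly.  With fewer than k stations all
    available ones are used (with a warning); with none, NaNs.
    """
    day = stations[stations["date"] == date]
    if len(day) == 0:
        return {c: float("nan") for c in WEATHER_VALUE_COLS}
    d = great_circle_km(target_lat, target_lon, day["lat"].to_numpy(), day["lon"].to_numpy())
    exact = d < 1e-3  # < 1 m
    if exact.any():
        row = day.iloc[int(np.argmax(exact))]
        return {c: float(row[c]) for c in WEATHER_VALUE_COLS}
    if len(day) < k:
        warnings.warn(
            f"only {len(day)} station(s) with data on {date}; using all", stacklevel=2
        )
        k = len(day)
    nearest = np.argsort(d)[:k]
    w = d[nearest] ** (-power)
    w = w / w.sum()
    return {c: float(w @ day.iloc[nearest][c].to_numpy(dtype=float)) for c in WEATHER_VALUE_COLS}


def _location_for_day(
    state: str,
    day: dt.date,
    home: tuple[float, float],
    den_records: pd.DataFrame | None,
    bear_id: str,
) -> tuple[float, float]:
    """Den coordinates during hibernation/transition, home range otherwise.

    ``den_records`` (bear_id, date, lat, lon) lists dens in occupancy
    order; a relocation switches coordinates from its recorded date on.
    """
    if state == "active" or den_records is None or len(den_records) == 0:
        return home
    dens = den_records[den_records["bear_id"] == bear_id].sort_values("date")
    if len(dens) == 0:
        return home
    occupied = dens[dens["date"] <= day]
    row = occupied.iloc[-1] if len(occupied) else dens.iloc[0]
    return float(row["lat"]), float(row["lon"])


def window_covariates(
    window: AnalysisWindow,
    weather: pd.DataFrame,
    metadata: pd.DataFrame,
    den_records: pd.DataFrame | None = None,
    home_location: tuple[float, float] = (61.0, 15.0),
    latitude_deg: float | None = None,
    k: int = 3,
    power: float = 2.0,
) -> dict:
    """Covariate record for one analysis window (one row of the model table).

    Environmental covariates are arithmetic means of the daily interpolated
    values over the window's days; day length uses the mean study latitude.
    Missing metadata fields pass through as NaN markers — the model stage
    drops incomplete rows.
    """
    if latitude_deg is None:
        latitude_deg = home_location[0]
    days = pd.date_range(window.start.date(), window.end.date() - dt.timedelta(days=1), freq="D")
    days = [d.date() for d in days]
    vals = {c: [] for c in WEATHER_VALUE_COLS}
    for day in days:
        lat, lon = _location_for_day(window.state, day, home_location, den_records, window.bear_id)
        est = idw_interpolate(weather, lat, lon, day, k=k, power=power)
        for c in WEATHER_VALUE_COLS:
            vals[c].append(est[c])
    dl = day_length(latitude_deg, np.array(days, dtype="datetime64[D]"))

    meta_row: dict = {}
    match = metadata[metadata["bear_id"] == window.bear_id]
    if len(match):
        meta_row = match.iloc[0].to_dict()

    return {
        "window_id": window.window_id,
        "bear_id": window.bear_id,
        "variable": window.variable,
        "state": window.state,
        "season": window.season,
        "ambient_temp": float(np.nanmean(vals["ta_mean"])) if len(days) else float("nan"),
        "snow_depth": float(np.nanmean(vals["snow_depth"])) if len(days) else float("nan"),
        "day_length": float(np.mean(dl)),
        "day_length_direction": day_length_direction(days[0], days[-1], latitude_deg),
        "den_type": meta_row.get("den_type", float("nan")),
        "open_area": meta_row.get("open_area", float("nan")),
        "body_mass": meta_row.get("body_mass", float("nan")),
        "sex": meta_row.get("sex", float("nan")),
        "age_class": meta_row.get("age_class", float("nan")),
        "status": meta_row.get("status", float("nan")),
    }


def covariate_table(
    windows: list[AnalysisWindow],
    weather: pd.DataFrame,
    metadata: pd.DataFrame,
    den_records: pd.DataFrame | None = None,
    home_location: tuple[float, float] = (61.0, 15.0),
    **kwargs,
) -> pd.DataFrame:
    """Covariate records for a list of windows, keyed by window id."""
    return pd.DataFrame(
        [
            window_covariates(
                w, weather, metadata, den_records, home_location, **kwargs
            )
            for w in windows
        ]
    )
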