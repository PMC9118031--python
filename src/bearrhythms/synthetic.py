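"""Synthetic bear-years, weather networks and rhythm cohorts.

Every downstream stage of the pipeline is exercised against data with
known ground truth, because the field recordings the analysis was designed
for are not publicly deposited.  The generator emulates their structure:

* body temperature sampled every 5–30 min, with diel (24 h) plus ultradian
  (12 h) components during the active state, a multiday oscillation at a
  depressed mean during hibernation, and linear daily-mean drifts through
  the den entry/exit transitions constructed so the detection thresholds
  (36.4 / 36.7 °C sustained for seven days) are crossed exactly on the
  configured dates;
* activity as 5-min summed bi-axial counts in [0, 510], built from a
  rectified sinusoid mixture with a crepuscular double peak, retaining a
  small diel component during hibernation;
* heart rate as 2-min means with the same seasonal architecture;
* AR(1)-correlated measurement noise, and data gaps of 14 days after each
  capture and 3 days after each disturbance.

Amplitudes and noise magnitudes are package defaults chosen to look like
published bear traces; they are free parameters of the simulation, not
measured values.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    ACTIVITY_MAX,
    DEFAULT_OFFSETS,
    STUDY_TZ,
    BiologgingSeries,
    TransitionOffsets,
)

STUDY_CENTER = (61.0, 15.0)  # latitude, longitude of the study area


@dataclass(frozen=True)
class VariableParams:
    """Generator settings for one biologging variable."""

    cadence_minutes: float
    active_mean: float
    hib_mean: float
    diel_amplitude: float
    ultradian_amplitude: float
    infradian_amplitude: float
    noise_sd: float
    ar1_coefficient: float = 0.8
    #: diel amplitude retained during hibernation (activity keeps a small
    #: 24 h component in the den; physiological variables drop theirs)
    hib_diel_amplitude: float = 0.0

    def __post_init__(self):
        if self.cadence_minutes <= 0:
            raise ValueError("cadence must be > 0")
        for a in ("diel_amplitude", "ultradian_amplitude", "infradian_amplitude", "noise_sd"):
            if getattr(self, a) < 0:
                raise ValueError(f"{a} must be >= 0")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")


DEFAULT_VARIABLE_PARAMS: dict[str, VariableParams] = {
    # Tb: ~37.3 °C active with a ~0.7 °C peak-to-trough diel swing,
    # hibernation plateau ~34.5 °C with a multiday oscillation
    "tb": VariableParams(20.0, 37.3, 34.5, 0.35, 0.15, 0.4, 0.15),
    # HR: tens of bpm active, deep bradycardia in the den
    "hr": VariableParams(2.0, 70.0, 15.0, 10.0, 5.0, 4.0, 5.0),
    # activity counts: crepuscular mixture, near-quiescent hibernation
    "activity": VariableParams(5.0, 90.0, 3.0, 60.0, 35.0, 0.0, 25.0, 0.8, 5.0),
}

ENTRY_THRESHOLD_C = 36.4
EXIT_THRESHOLD_C = 36.7


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition settings for a simulated cohort of bear-years."""

    n_bears: int = 5
    start_date: dt.date = dt.date(2015, 5, 1)
    end_date: dt.date = dt.date(2016, 7, 31)
    den_entry_day: dt.date = dt.date(2015, 11, 1)
    den_exit_day: dt.date = dt.date(2016, 4, 10)
    #: per-bear jitter (days) applied alternately +/- around the den dates
    den_date_jitter_days: int = 6
    variable_params: dict[str, VariableParams] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_PARAMS)
    )
    infradian_period_hours: float = 120.0
    transition_offsets: dict[str, TransitionOffsets] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    capture_dates: tuple[dt.date, ...] = ()
    disturbance_dates: tuple[dt.date, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if (self.end_date - self.start_date).days < 60:
            raise ValueError("date span must be at least 60 days")
        if self.den_entry_day is not None and self.den_exit_day is not None:
            if self.den_entry_day >= self.den_exit_day:
                raise ValueError("den entry must precede den exit")
            if not (self.start_date < self.den_entry_day < self.end_date):
                raise ValueError("den entry outside the simulated span")
            if not (self.start_date < self.den_exit_day < self.end_date):
                raise ValueError("den exit outside the simulated span")


@dataclass
class GroundTruth:
    """What the generator planted, for verification by downstream stages."""

    bear_id: str
    den_entry: dt.date | None
    den_exit: dt.date | None
    #: dominant period (hours) and rhythm class per (variable, regime)
    dominant_period_hours: dict[tuple[str, str], float] = field(default_factory=dict)
    true_class: dict[tuple[str, str], str] = field(default_factory=dict)
    #: multinomial cohort simulation: generating probabilities per row
    class_probabilities: np.ndarray | None = None
    coefficients: np.ndarray | None = None


def _bear_den_dates(config: SimulationConfig, bear_index: int) -> tuple[dt.date, dt.date]:
    if config.den_date_jitter_days == 0 or config.n_bears == 1:
        return config.den_entry_day, config.den_exit_day
    rng = np.random.default_rng((config.seed, 7, bear_index))
    j1 = int(rng.integers(-config.den_date_jitter_days, config.den_date_jitter_days + 1))
    j2 = int(rng.integers(-config.den_date_jitter_days, config.den_date_jitter_days + 1))
    return (
        config.den_entry_day + dt.timedelta(days=j1),
        config.den_exit_day + dt.timedelta(days=j2),
    )


def _daily_mean_trajectory(
    dates: np.ndarray,
    entry: dt.date,
    exit: dt.date,
    offsets: TransitionOffsets,
    active_mean: float,
    hib_mean: float,
    threshold_anchors: bool,
) -> np.ndarray:
    """Piecewise-linear daily mean level across the bear-year.

    For Tb (``threshold_anchors``) the decline is anchored so the daily
    mean equals 36.4 °C exactly on the den-entry day and 36.7 °C exactly
    on the den-exit day, which makes the seven-day threshold detectors
    recover the planted dates exactly in the noise-free limit.
    """
    t = np.array([(pd.Timestamp(d).date() - entry).days for d in dates], dtype=float)
    te = float((exit - entry).days)
    pre_in, post_in = offsets.pre_entry_days, max(offsets.post_entry_days, 1)
    pre_out, post_out = offsets.pre_exit_days, max(offsets.post_exit_days, 1)

    if threshold_anchors:
        knots_x = [-pre_in, 0.0, post_in, te - pre_out, te, te + post_out]
        knots_y = [active_mean, ENTRY_THRESHOLD_C, hib_mean, hib_mean, EXIT_THRESHOLD_C, active_mean]
    else:
        knots_x = [-pre_in, post_in, te - pre_out, te + post_out]
        knots_y = [active_mean, hib_mean, hib_mean, active_mean]
    return np.interp(t, knots_x, knots_y, left=active_mean, right=active_mean)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_bear_year(
    config: SimulationConfig,
    bear_id: str,
    bear_index: int = 0,
    variables: tuple[str, ...] = ("tb", "hr", "activity"),
) -> tuple[dict[str, BiologgingSeries], GroundTruth]:
    """Generate one bear's year of biologging series plus its ground truth.

    The oscillation regime switches with the seasonal state: the diel plus
    ultradian mixture runs up to den entry and from den exit on (its daily
    mean is exactly zero, so the threshold detectors stay exact), the
    multiday component runs only over the hibernation core, and the drift
    zones in between carry no oscillation.
    """
    entry, exit = (
        _bear_den_dates(config, bear_index)
        if config.den_entry_day is not None
        else (None, None)
    )
    truth = GroundTruth(bear_id=bear_id, den_entry=entry, den_exit=exit)
    series: dict[str, BiologgingSeries] = {}

    t0 = pd.Timestamp(config.start_date, tz=STUDY_TZ)
    t1 = pd.Timestamp(config.end_date, tz=STUDY_TZ)

    for var in variables:
        p = config.variable_params[var]
        idx = pd.date_range(t0, t1, freq=pd.Timedelta(minutes=p.cadence_minutes), inclusive="left")
        hours = (idx.asi8 - idx.asi8[0]) / 3.6e12
        dates = idx.normalize()

        offs = config.transition_offsets[var]
        if entry is not None:
            level = _daily_mean_trajectory(
                dates.date, entry, exit, offs, p.active_mean, p.hib_mean, var == "tb"
            )
            days_from_entry = np.array([(d - entry).days for d in dates.date], dtype=float)
            days_from_exit = np.array([(d - exit).days for d in dates.date], dtype=float)
            in_active_osc = (days_from_entry < 0) | (days_from_exit >= 0)
            hib_lo, hib_hi = max(offs.post_entry_days, 1), offs.pre_exit_days
            in_hib_osc = (days_from_entry >= hib_lo) & (days_from_exit < -hib_hi)
        else:
            level = np.full(len(idx), p.active_mean)
            in_active_osc = np.ones(len(idx), dtype=bool)
            in_hib_osc = np.zeros(len(idx), dtype=bool)

        w24 = 2.0 * np.pi / 24.0
        w12 = 2.0 * np.pi / 12.0
        winf = 2.0 * np.pi / config.infradian_period_hours
        osc = np.zeros(len(idx))
        # active: diel peak in the evening plus a 12 h harmonic -> the
        # crepuscular double peak seen in raw actograms
        osc[in_active_osc] = p.diel_amplitude * np.sin(w24 * hours[in_active_osc]) + (
            p.ultradian_amplitude * np.sin(w12 * hours[in_active_osc] + 0.7)
        )
        osc[in_hib_osc] = p.infradian_amplitude * np.sin(winf * hours[in_hib_osc]) + (
            p.hib_diel_amplitude * np.sin(w24 * hours[in_hib_osc])
        )

        rng = np.random.default_rng(
            (config.seed, bear_index, {"tb": 1, "hr": 2, "activity": 3}[var])
        )
        noise = _ar1_noise(rng, len(idx), p.noise_sd, p.ar1_coefficient)
        values = level + osc + noise

        if var == "activity":
            values = np.clip(np.rint(np.maximum(values, 0.0)), 0, ACTIVITY_MAX)

        keep = np.ones(len(idx), dtype=bool)
        for d, days in (
            *((c, 14) for c in config.capture_dates),
            *((c, 3) for c in config.disturbance_dates),
        ):
            lo = pd.Timestamp(d, tz=STUDY_TZ)
            keep &= ~((idx >= lo) & (idx < lo + pd.Timedelta(days=days)))

        series[var] = BiologgingSeries(
            bear_id=bear_id,
            variable=var,
            timestamps=idx[keep],
            values=values[keep],
            cadence_minutes=p.cadence_minutes,
        )

        dominant_active = "diel" if p.diel_amplitude >= p.ultradian_amplitude else "ultradian"
        truth.dominant_period_hours[(var, "active")] = (
            24.0 if dominant_active == "diel" else 12.0
        )
        truth.true_class[(var, "active")] = dominant_active
        if p.infradian_amplitude >= p.hib_diel_amplitude:
            truth.dominant_period_hours[(var, "hibernation")] = config.infradian_period_hours
            truth.true_class[(var, "hibernation")] = "infradian"
        else:
            truth.dominant_period_hours[(var, "hibernation")] = 24.0
            truth.true_class[(var, "hibernation")] = "diel"

    return series, truth


def simulate_cohort(
    config: SimulationConfig, variables: tuple[str, ...] = ("tb", "hr", "activity")
) -> tuple[dict[str, dict[str, BiologgingSeries]], dict[str, GroundTruth]]:
    """All bears of a configured cohort: {bear_id: {variable: series}}."""
    all_series: dict[str, dict[str, BiologgingSeries]] = {}
    truths: dict[str, GroundTruth] = {}
    for i in range(config.n_bears):
        bear_id = f"bear{i + 1:02d}"
        s, t = simulate_bear_year(config, bear_id, i, variables)
        all_series[bear_id] = s
        truths[bear_id] = t
    return all_series, truths


# ---------------------------------------------------------------------------
# weather


def simulate_weather(
    start_date: dt.date,
    end_date: dt.date,
    n_stations: int = 3,
    seed: int = 0,
    center: tuple[float, float] = STUDY_CENTER,
    spread_deg: float = 1.0,
) -> pd.DataFrame:
    """Daily records for a network of weather stations around the study area.

    Mean ambient temperature follows a seasonal sinusoid spanning roughly
    -14 to +18 °C (min/max offset by ±4 °C); snow depth is exactly zero
    from June through September and rises smoothly to at most 0.63 m in
    late winter.  Deterministic for a fixed seed.
    """
    if n_stations < 3:
        raise ValueError("need at least 3 stations for 3-nearest IDW")
    rng = np.random.default_rng((seed, 99))
    days = pd.date_range(start_date, end_date, freq="D")
    doy = days.dayofyear.to_numpy(dtype=float)

    rows = []
    for s in range(n_stations):
        lat = center[0] + rng.uniform(-spread_deg, spread_deg)
        lon = center[1] + rng.uniform(-2 * spread_deg, 2 * spread_deg)
        # coldest around late January (doy ~ 25), warmest in July
        ta_mean = 2.0 + 16.0 * np.cos(2.0 * np.pi * (doy - 205.0) / 365.25)
        ta_mean = ta_mean + rng.normal(0.0, 1.0, len(days))
        ta_mean = np.clip(ta_mean, -15.4, 19.1)
        # snow: smooth winter bump peaking mid-February, identically 0
        # June-September
        delta = (doy - 45.0 + 182.625) % 365.25 - 182.625
        bump = 0.70 * np.exp(-0.5 * (delta / 50.0) ** 2)
        snow = np.clip(bump - 0.05 + rng.normal(0.0, 0.01, len(days)), 0.0, 0.63)
        snow[(doy >= 152) & (doy <= 273)] = 0.0
        rows.append(
            pd.DataFrame(
                {
                    "station_id": f"station{s + 1:02d}",
                    "lat": lat,
                    "lon": lon,
                    "date": [d.date() for d in days],
                    "ta_min": ta_mean - 4.0,
                    "ta_mean": ta_mean,
                    "ta_max": ta_mean + 4.0,
                    "snow_depth": snow,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Per-bear intrinsic attributes drawn from field-plausible ranges."""
    rng = np.random.default_rng((config.seed, 5))
    den_types = ("anthill", "nest", "rock", "soil", "uprooted tree")
    rows = []
    for i in range(config.n_bears):
        sex = rng.choice(["F", "M"])
        age_class = rng.choice(["adult", "subadult"], p=[0.7, 0.3])
        status = (
            rng.choice(["solitary", "pregnant", "with cubs"], p=[0.5, 0.25, 0.25])
            if sex == "F" and age_class == "adult"
            else "solitary"
        )
        rows.append(
            {
                "bear_id": f"bear{i + 1:02d}",
                "sex": sex,
                "age_class": age_class,
                "status": status,
                "body_mass": float(np.round(rng.uniform(17, 233), 1)),
                "den_type": rng.choice(den_types),
                "open_area": float(np.round(rng.uniform(1, 100), 1)),
                "den_lat": STUDY_CENTER[0] + rng.uniform(-0.5, 0.5),
                "den_lon": STUDY_CENTER[1] + rng.uniform(-1.0, 1.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rhythm cohorts for the multinomial model


def simulate_rhythm_cohort(
    n_windows: int,
    true_coefficients: np.ndarray,
    covariate_distributions: dict[str, tuple[float, float]],
    seed: int = 0,
    classes: tuple[str, ...] = ("diel", "ultradian", "infradian", "arrhythmic"),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a covariate table and class labels from a known multinomial model.

    ``true_coefficients`` has shape (1 + n_covariates, K - 1): the first
    row holds intercepts, later rows the slopes for each covariate (in
    dict order), each column the contrast of one non-reference class
    against the first entry of ``classes``.  Covariates are sampled
    uniformly from the given (low, high) ranges.  The generating per-row
    probabilities are retained in the returned :class:`GroundTruth`.
    """
    names = list(covariate_distributions)
    coef = np.asarray(true_coefficients, dtype=float)
    K = len(classes)
    if coef.shape != (1 + len(names), K - 1):
        raise ValueError(
            f"coefficient matrix must be {(1 + len(names), K - 1)}, got {coef.shape}"
        )
    rng = np.random.default_rng(seed)
    data = {
        name: rng.uniform(lo, hi, n_windows) for name, (lo, hi) in covariate_distributions.items()
    }
    X = np.column_stack([np.ones(n_windows)] + [data[n] for n in names])
    eta = X @ coef
    full = np.concatenate([np.zeros((n_windows, 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.uniform(size=(n_windows, 1))
    labels = np.asarray(classes)[(u > cum).sum(axis=1)]
    df = pd.DataFrame(data)
    df["rhythm_class"] = labels
    truth = GroundTruth(
        bear_id="cohort",
        den_entry=None,
        den_exit=None,
        class_probabilities=probs,
        coefficients=coef,
    )
    return df, truth
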