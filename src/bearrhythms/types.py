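"""Shared domain containers for the rhythm-analysis pipeline."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed civil time zone of the study area (UTC+1, no DST).
STUDY_TZ = "Etc/GMT-1"

#: Recognised biologging variables.
VARIABLES = ("tb", "hr", "activity")

#: Seasonal state labels, in within-year order.
STATES = ("active", "transition_entry", "hibernation", "transition_exit")

#: Rhythm classes assigned to analysis windows.
RHYTHM_CLASSES = ("ultradian", "diel", "infradian", "arrhythmic")

#: Maximum value of the summed bi-axial activity counts (two 0–255 axes).
ACTIVITY_MAX = 510


@dataclass
class BiologgingSeries:
    """One variable's irregular time series for one bear.

    Values carry the variable's native units: °C for ``tb``, beats/min for
    ``hr``, summed acceleration counts in [0, 510] for ``activity``.  Gaps
    are absent rows; no NaN is ever stored.
    """

    bear_id: str
    variable: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    cadence_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.timestamps.tz is None:
            self.timestamps = self.timestamps.tz_localize(STUDY_TZ)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if (deltas <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("series must not contain NaN (gaps are absent rows)")

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, timestamps: pd.DatetimeIndex, values: np.ndarray) -> "BiologgingSeries":
        return BiologgingSeries(
            bear_id=self.bear_id,
            variable=self.variable,
            timestamps=timestamps,
            values=values,
            cadence_minutes=self.cadence_minutes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bear_id": self.bear_id,
                "timestamp": self.timestamps,
                "variable": self.variable,
                "value": self.values,
            }
        )


@dataclass(frozen=True)
class TransitionOffsets:
    """Whole-day extents of the transition states around den entry and exit.

    ``pre_entry_days`` days before den entry to ``post_entry_days`` after it
    form the entry transition; likewise around den exit.  The drop in each
    variable starts at a variable-specific lead before the den dates and
    continues beyond them, so each variable carries its own offsets.
    """

    pre_entry_days: int
    post_entry_days: int
    pre_exit_days: int
    post_exit_days: int

    def __post_init__(self) -> None:
        for name in ("pre_entry_days", "post_entry_days", "pre_exit_days", "post_exit_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Published leads: Tb / HR / activity begin to decrease 13 / 24 / 25 days
# before den entry and to increase 33 / 63 / 10 days before den exit; Tb
# keeps decreasing 30 days and activity 9 days past entry.  Post-entry for
# HR and the post-exit extents are package defaults, configurable.
DEFAULT_OFFSETS: dict[str, TransitionOffsets] = {
    "tb": TransitionOffsets(13, 30, 33, 0),
    "hr": TransitionOffsets(24, 30, 63, 0),
    "activity": TransitionOffsets(25, 9, 10, 0),
}


@dataclass(frozen=True)
class StateInterval:
    """A half-open run of calendar days [start, end) in one seasonal state."""

    state: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.end <= self.start:
            raise ValueError("interval must be non-empty (end > start)")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days


@dataclass
class SeasonalStateMap:
    """Den phenology plus per-variable labeled state intervals for one bear."""

    bear_id: str
    den_entry: dt.date | None
    den_exit: dt.date | None
    intervals: dict[str, list[StateInterval]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bear_id": self.bear_id,
                "variable": var,
                "state": iv.state,
                "start_date": iv.start,
                "end_date": iv.end,
            }
            for var, ivs in self.intervals.items()
            for iv in ivs
        ]
        return pd.DataFrame(rows, columns=["bear_id", "variable", "state", "start_date", "end_date"])


@dataclass
class AnalysisWindow:
    """A 15–25-day slice of one series within one seasonal state."""

    bear_id: str
    variable: str
    state: str
    start: pd.Timestamp
    end: pd.Timestamp
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    season: int

    @property
    def duration_days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)

    @property
    def window_id(self) -> str:
        return f"{self.bear_id}:{self.variable}:{self.start.date().isoformat()}"

    @property
    def hours_since_start(self) -> np.ndarray:
        """Sample times in hours from the window start (the LSP time axis)."""
        return (self.timestamps.asi8 - self.start.value) / 3.6e12

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RhythmCall:
    """Highest-peak periodogram classification of one analysis window."""

    window_id: str
    rhythm_class: str
    peak_period_hours: float
    peak_power: float
    p_value: float

    def __post_init__(self) -> None:
        if self.rhythm_class not in RHYTHM_CLASSES:
            raise ValueError(f"unknown rhythm class {self.rhythm_class!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
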