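"""Exclusion filtering and tiling of seasonal states into analysis windows.

Rhythm detection needs at least ten cycles of a diel rhythm — ten days —
so states are tiled into consecutive 25-day windows from the state's
start (long enough to also see multiday rhythms); a
terminal remainder is kept only if it spans at least 15 days.  Windows that
contain (or start/end in) a sampling gap longer than two days are dropped
— such gaps originate from capture and disturbance exclusions and would
corrupt the periodogram.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import STUDY_TZ, AnalysisWindow, BiologgingSeries, StateInterval

TB_PLAUSIBLE_MIN_C = 30.0
CAPTURE_EXCLUSION_DAYS = 14
DISTURBANCE_EXCLUSION_DAYS = 3

WINDOW_DAYS = 25
MIN_WINDOW_DAYS = 15
MAX_GAP_DAYS = 2.0
MIN_SAMPLES = 8


@dataclass
class ExclusionLog:
    """Counts of samples removed per exclusion rule."""

    n_input: int = 0
    n_tb_implausible: int = 0
    n_capture: int = 0
    n_disturbance: int = 0

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_tb_implausible - self.n_capture - self.n_disturbance


@dataclass
class WindowLog:
    """Why candidate windows were discarded during tiling."""

    n_windows: int = 0
    dropped_gap: int = 0
    dropped_short_state: int = 0
    dropped_few_samples: int = 0
    records: list[str] = field(default_factory=list)


def apply_exclusions(
    series: BiologgingSeries,
    capture_dates: list[dt.date] | None = None,
    disturbance_dates: list[dt.date] | None = None,
    tb_min: float = TB_PLAUSIBLE_MIN_C,
) -> tuple[BiologgingSeries, ExclusionLog]:
    """Drop implausible Tb readings and post-event recovery periods.

    Tb values strictly below ``tb_min`` (sensor artefacts / peri-capture
    hypothermia) are removed from Tb series only.  All samples within
    [capture, capture + 14 d) and [disturbance, disturbance + 3 d) are
    removed from every variable.  Boundary values are kept: Tb == 30.0 °C
    stays in.
    """
    log = ExclusionLog(n_input=len(series))
    keep = np.ones(len(series), dtype=bool)

    if series.variable == "tb":
        bad = series.values < tb_min
        log.n_tb_implausible = int(bad.sum())
        keep &= ~bad

    for dates, days, attr in (
        (capture_dates or [], CAPTURE_EXCLUSION_DAYS, "n_capture"),
        (disturbance_dates or [], DISTURBANCE_EXCLUSION_DAYS, "n_disturbance"),
    ):
        hit = np.zeros(len(series), dtype=bool)
        for d in dates:
            lo = pd.Timestamp(d, tz=STUDY_TZ)
            hi = lo + pd.Timedelta(days=days)
            hit |= (series.timestamps >= lo) & (series.timestamps < hi)
        removed = hit & keep
        setattr(log, attr, int(removed.sum()))
        keep &= ~hit

    return series.replace(series.timestamps[keep], series.values[keep]), log


def _has_long_gap(
    ts_ns: np.ndarray, start_ns: int, end_ns: int, max_gap_days: float
) -> bool:
    """True if [start, end) contains an internal or boundary gap > max_gap_days."""
    gap_ns = max_gap_days * 86400 * 1e9
    if len(ts_ns) == 0:
        return True
    edges = np.concatenate(([start_ns], ts_ns, [end_ns]))
    return bool((np.diff(edges) > gap_ns).any())


def tile_windows(
    intervals: list[StateInterval],
    series: BiologgingSeries,
    den_entry: dt.date | None = None,
    window_days: int = WINDOW_DAYS,
    min_days: int = MIN_WINDOW_DAYS,
    max_gap_days: float = MAX_GAP_DAYS,
    min_samples: int = MIN_SAMPLES,
) -> tuple[list[AnalysisWindow], WindowLog]:
    """Tile each state interval into analysis windows.

    The beginning of a state starts a new window; full ``window_days``
    windows follow consecutively and a terminal remainder is kept iff it
    spans at least ``min_days``.  Windows containing a sampling gap longer
    than ``max_gap_days`` (including gaps at either boundary) are discarded
    and logged, as are windows with fewer than ``min_samples`` samples.

    Season identifier: calendar year of the window start for active
    windows; the den-entry year for hibernation and transition windows of
    that winter (one hibernation spans the year boundary).
    """
    log = WindowLog()
    windows: list[AnalysisWindow] = []
    ts_ns = series.timestamps.asi8

    for iv in intervals:
        n_days = iv.n_days
        if n_days < min_days:
            log.dropped_short_state += 1
            log.records.append(f"{series.variable}/{iv.state} {iv.start}: state {n_days} d < {min_days} d")
            continue
        starts = list(range(0, n_days - n_days % window_days, window_days))
        remainder = n_days % window_days
        lengths = [window_days] * len(starts)
        if remainder >= min_days:
            starts.append(n_days - remainder)
            lengths.append(remainder)
        elif remainder > 0:
            log.records.append(
                f"{series.variable}/{iv.state} {iv.start}: {remainder} d remainder dropped"
            )
        for off, length in zip(starts, lengths):
            w_start = pd.Timestamp(iv.start + dt.timedelta(days=off), tz=STUDY_TZ)
            w_end = pd.Timestamp(iv.start + dt.timedelta(days=off + length), tz=STUDY_TZ)
            lo, hi = np.searchsorted(ts_ns, [w_start.value, w_end.value])
            sub_ns = ts_ns[lo:hi]
            if _has_long_gap(sub_ns, w_start.value, w_end.value, max_gap_days):
                log.dropped_gap += 1
                log.records.append(
                    f"{series.variable}/{iv.state} window {w_start.date()}: gap > {max_gap_days} d"
                )
                continue
            if hi - lo < min_samples:
                log.dropped_few_samples += 1
                continue
            if iv.state == "active" or den_entry is None:
                season = w_start.year
            else:
                season = den_entry.year
            windows.append(
                AnalysisWindow(
                    bear_id=series.bear_id,
                    variable=series.variable,
                    state=iv.state,
                    start=w_start,
                    end=w_end,
                    timestamps=series.timestamps[lo:hi],
                    values=series.values[lo:hi],
                    season=season,
                )
            )
    log.n_windows = len(windows)
    return windows, log


def windows_to_frame(windows: list[AnalysisWindow]) -> pd.DataFrame:
    """Tabular summary of windows (one row each), for CSV output."""
    rows = [
        {
            "window_id": w.window_id,
            "bear_id": w.bear_id,
            "variable": w.variable,
            "state": w.state,
            "start": w.start.isoformat(),
            "end": w.end.isoformat(),
            "season": w.season,
            "n_samples": len(w),
            "duration_days": w.duration_days,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "window_id",
            "bear_id",
            "variable",
            "state",
            "start",
            "end",
            "season",
            "n_samples",
            "duration_days",
        ],
    )
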