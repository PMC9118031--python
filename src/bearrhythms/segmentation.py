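"""Den phenology detection and seasonal-state assignment.

Den entry is the first autumn day on which the daily mean body temperature
stays at or below 36.4 °C for seven consecutive observed days; den exit is
the first spring day on which it stays at or above 36.7 °C for seven
consecutive observed days.  States are then labeled per variable with
variable-specific transition extents around those two dates, because body
temperature, heart rate and activity start their seasonal drift at
different leads.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .types import (
    DEFAULT_OFFSETS,
    BiologgingSeries,
    SeasonalStateMap,
    StateInterval,
    TransitionOffsets,
)

ENTRY_THRESHOLD_C = 36.4
EXIT_THRESHOLD_C = 36.7
RUN_DAYS = 7

# "In autumn" / "in spring" operationalised as search windows; month-day
# bounds, inclusive, applied within the series' span.
ENTRY_SEARCH = ((8, 1), (1, 31))  # Aug 1 .. Jan 31 (wraps the year end)
EXIT_SEARCH = ((2, 1), (7, 31))  # Feb 1 .. Jul 31


def daily_means(series: BiologgingSeries) -> pd.DataFrame:
    """Arithmetic mean per calendar date; one row per date with >= 1 sample.

    Returns columns ``date`` (``datetime.date``), ``mean``, ``n``.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    dates = series.timestamps.date
    df = pd.DataFrame({"date": dates, "value": series.values})
    out = df.groupby("date", sort=True)["value"].agg(["mean", "count"]).reset_index()
    out.columns = ["date", "mean", "n"]
    return out


def _first_run_date(
    daily: pd.DataFrame,
    predicate,
    search_start: dt.date,
    search_end: dt.date,
    run_days: int = RUN_DAYS,
) -> dt.date | None:
    """First date d in [search_start, search_end] with d..d+run_days-1 all
    observed and satisfying ``predicate``.  A missing daily mean breaks a
    run: the definition requires seven observed daily means."""
    by_date = daily.set_index("date")["mean"]
    ok = {d: bool(predicate(v)) for d, v in by_date.items()}
    d = search_start
    one = dt.timedelta(days=1)
    while d <= search_end:
        run = [d + dt.timedelta(days=i) for i in range(run_days)]
        if all(ok.get(r, False) for r in run):
            return d
        d += one
    return None


def _resolve_search(
    daily: pd.DataFrame,
    search_window: tuple[dt.date, dt.date] | None,
    month_day_bounds: tuple[tuple[int, int], tuple[int, int]],
) -> tuple[dt.date, dt.date]:
    if search_window is not None:
        return search_window
    dates = daily["date"]
    lo, hi = dates.min(), dates.max()
    (m0, d0), (m1, d1) = month_day_bounds
    wraps = (m1, d1) < (m0, d0)
    # first yearly occurrence of the month-day window intersecting the span
    for year in range(lo.year - 1, hi.year + 1):
        start = dt.date(year, m0, d0)
        end = dt.date(year + 1 if wraps else year, m1, d1)
        if end >= lo and start <= hi:
            return max(start, lo), min(end, hi)
    return lo, hi


def detect_den_entry(
    daily_tb: pd.DataFrame,
    search_window: tuple[dt.date, dt.date] | None = None,
    threshold: float = ENTRY_THRESHOLD_C,
    run_days: int = RUN_DAYS,
) -> dt.date | None:
    """First date whose daily mean Tb is <= ``threshold`` for ``run_days``
    consecutive observed days, searched within ``search_window`` (default:
    Aug 1 – Jan 31 inside the table's span).  ``None`` if no such run."""
    start, end = _resolve_search(daily_tb, search_window, ENTRY_SEARCH)
    return _first_run_date(daily_tb, lambda v: v <= threshold, start, end, run_days)


def detect_den_exit(
    daily_tb: pd.DataFrame,
    search_window: tuple[dt.date, dt.date] | None = None,
    threshold: float = EXIT_THRESHOLD_C,
    run_days: int = RUN_DAYS,
) -> dt.date | None:
    """Mirror of :func:`detect_den_entry` with daily mean >= ``threshold``,
    searched within Feb 1 – Jul 31 by default."""
    start, end = _resolve_search(daily_tb, search_window, EXIT_SEARCH)
    return _first_run_date(daily_tb, lambda v: v >= threshold, start, end, run_days)


def assign_states(
    entry: dt.date | None,
    exit: dt.date | None,
    variable: str,
    span: tuple[dt.date, dt.date],
    offsets: TransitionOffsets | None = None,
) -> tuple[list[StateInterval], list[str]]:
    """Label the half-open day span [span_start, span_end) with seasonal states.

    transition_entry = [entry - pre_entry, entry + post_entry),
    transition_exit  = [exit - pre_exit, exit + post_exit),
    hibernation between them, active elsewhere.  If either den date is
    absent the whole span is active.  Overlapping transitions (a short
    hibernation) are truncated at their midpoint and a warning recorded.

    Returns (intervals, warnings).
    """
    if offsets is None:
        offsets = DEFAULT_OFFSETS[variable]
    span_start, span_end = span
    if span_end <= span_start:
        raise ValueError("empty span")
    warnings: list[str] = []
    if entry is None or exit is None:
        return [StateInterval("active", span_start, span_end)], warnings
    if entry >= exit:
        raise ValueError(f"den entry {entry} must precede den exit {exit}")

    te_start = entry - dt.timedelta(days=offsets.pre_entry_days)
    te_end = entry + dt.timedelta(days=offsets.post_entry_days)
    tx_start = exit - dt.timedelta(days=offsets.pre_exit_days)
    tx_end = exit + dt.timedelta(days=offsets.post_exit_days)

    if te_end > tx_start:
        mid = te_start + (tx_end - te_start) / 2
        mid = dt.date(mid.year, mid.month, mid.day)
        mid = min(max(mid, te_start), tx_end)
        warnings.append(
            f"{variable}: transitions overlap (entry ends {te_end}, exit starts "
            f"{tx_start}); truncated at {mid}"
        )
        te_end = tx_start = mid

    cuts = [span_start, te_start, te_end, tx_start, tx_end, span_end]
    labels = ["active", "transition_entry", "hibernation", "transition_exit", "active"]
    intervals: list[StateInterval] = []
    for (a, b), lab in zip(zip(cuts[:-1], cuts[1:]), labels):
        a, b = max(a, span_start), min(b, span_end)
        if b > a:
            intervals.append(StateInterval(lab, a, b))
    return intervals, warnings


def build_state_map(
    tb_series: BiologgingSeries,
    variables: dict[str, BiologgingSeries],
    offsets: dict[str, TransitionOffsets] | None = None,
    entry_search: tuple[dt.date, dt.date] | None = None,
    exit_search: tuple[dt.date, dt.date] | None = None,
    entry_threshold: float = ENTRY_THRESHOLD_C,
    exit_threshold: float = EXIT_THRESHOLD_C,
) -> SeasonalStateMap:
    """Detect den entry/exit from Tb and label every supplied variable."""
    offsets = offsets or DEFAULT_OFFSETS
    daily = daily_means(tb_series)
    entry = detect_den_entry(daily, entry_search, entry_threshold)
    exit_search_eff = exit_search
    if exit_search_eff is None and entry is not None:
        # Search for exit strictly after entry so an early warm spell in the
        # same spring the record starts in cannot masquerade as den exit.
        exit_search_eff = (
            max(entry + dt.timedelta(days=1), dt.date(entry.year + 1, 2, 1)),
            dt.date(entry.year + 1, 7, 31),
        )
    exit = detect_den_exit(daily, exit_search_eff, exit_threshold)
    smap = SeasonalStateMap(bear_id=tb_series.bear_id, den_entry=entry, den_exit=exit)
    for var, series in variables.items():
        span = (series.timestamps[0].date(), series.timestamps[-1].date() + dt.timedelta(days=1))
        ivs, warns = assign_states(entry, exit, var, span, offsets.get(var))
        smap.intervals[var] = ivs
        smap.warnings.extend(warns)
    return smap
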