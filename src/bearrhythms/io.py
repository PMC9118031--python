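"""CSV formats and pipeline configuration.

All tabular input and output is plain CSV with a one-line header so every
artifact stays inspectable.  The long series format has columns
``bear_id, timestamp, variable, value`` with ISO 8601 timestamps.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ACTIVITY_MAX, STUDY_TZ, VARIABLES, BiologgingSeries

SERIES_COLUMNS = ["bear_id", "timestamp", "variable", "value"]


class SeriesFormatError(ValueError):
    pass


def read_series_csv(path: str | Path) -> list[BiologgingSeries]:
    """Read a long-format series CSV into validated series objects.

    Rows are sorted per (bear, variable); duplicate timestamps within one
    series and activity values outside [0, 510] are rejected with the
    offending row numbers (first 10 listed).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise SeriesFormatError(f"missing column(s): {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = df.index[ts.isna() | df["value"].isna()].tolist()
    if bad:
        raise SeriesFormatError(f"unparseable rows (first 10): {bad[:10]}")
    unknown = df.index[~df["variable"].isin(VARIABLES)].tolist()
    if unknown:
        raise SeriesFormatError(f"unknown variable in rows (first 10): {unknown[:10]}")
    is_act = df["variable"] == "activity"
    out_of_range = df.index[
        is_act & ((df["value"] < 0) | (df["value"] > ACTIVITY_MAX))
    ].tolist()
    if out_of_range:
        raise SeriesFormatError(
            f"activity values outside [0, {ACTIVITY_MAX}] in rows (first 10): "
            f"{out_of_range[:10]}"
        )
    df = df.assign(_ts=ts.dt.tz_convert(STUDY_TZ))

    series = []
    for (bear, var), grp in df.groupby(["bear_id", "variable"], sort=True):
        grp = grp.sort_values("_ts")
        dup = grp.index[grp["_ts"].duplicated()].tolist()
        if dup:
            raise SeriesFormatError(
                f"duplicate timestamps for {bear}/{var} in rows (first 10): {dup[:10]}"
            )
        series.append(
            BiologgingSeries(
                bear_id=str(bear),
                variable=str(var),
                timestamps=pd.DatetimeIndex(grp["_ts"]),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return series


def write_series_csv(series: list[BiologgingSeries], path: str | Path) -> None:
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SERIES_COLUMNS)
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S%z")
    df.to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"station_id", "lat", "lon", "date", "ta_min", "ta_mean", "ta_max", "snow_depth"}
    missing = need - set(df.columns)
    if missing:
        raise SeriesFormatError(f"weather CSV missing column(s): {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "bear_id" not in df.columns:
        raise SeriesFormatError("metadata CSV needs a bear_id column")
    return df


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Capture/disturbance events: columns bear_id, date, event_type."""
    df = pd.read_csv(path)
    need = {"bear_id", "date", "event_type"}
    if need - set(df.columns):
        raise SeriesFormatError(f"events CSV needs columns {sorted(need)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis chain in one place."""

    entry_threshold: float = 36.4
    exit_threshold: float = 36.7
    run_days: int = 7
    window_days: int = 25
    min_window_days: int = 15
    max_gap_days: float = 2.0
    alpha: float = 0.01
    oversampling: int = 4
    min_period_hours: float = 2.0
    max_period_hours: float = 168.0
    idw_k: int = 3
    idw_power: float = 2.0
    latitude: float = 61.0
    longitude: float = 15.0
    bin_minutes: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.entry_threshold >= self.exit_threshold:
            raise ValueError("entry threshold must be below exit threshold")
        if not self.min_period_hours < 18.0 < 36.0 < self.max_period_hours:
            raise ValueError("period band edges must satisfy min < 18 < 36 < max")
        if self.min_window_days > self.window_days:
            raise ValueError("min window length exceeds the window length")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunLog:
    """Per-stage record counts and warnings for one pipeline run."""

    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                default=str,
            )
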