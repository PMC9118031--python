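"""End-to-end pipeline driver.

Stage order: exclusions -> daily means -> den detection -> states ->
windows -> spectral calls -> covariates -> state model -> report tables.
Each stage's output is persisted as CSV and the run log records counts in
and out; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from . import covariates as cov
from . import report, rhythm_model, segmentation, spectral, windowing
from .io import PipelineConfig, RunLog
from .synthetic import GroundTruth, SimulationConfig, simulate_cohort, simulate_metadata, simulate_weather
from .types import BiologgingSeries


def run_pipeline(
    series_by_bear: dict[str, dict[str, BiologgingSeries]],
    weather: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    events: pd.DataFrame | None = None,
    fit_state_model: bool = True,
) -> dict:
    """Run the full analysis chain on prepared series.

    Returns a dict with the states/windows/calls/covariates/summary tables
    (and, when fitted, the state model) plus the run log.  If ``out_dir``
    is given every table is written there as CSV.
    """
    log = RunLog(config_hash=config.config_hash(), seed=config.seed)

    all_states, all_windows, all_calls, window_objects = [], [], [], []
    n_in = n_kept = 0
    for bear_id, variables in sorted(series_by_bear.items()):
        captures, disturbances = [], []
        if events is not None:
            ev = events[events["bear_id"] == bear_id]
            captures = ev.loc[ev["event_type"] == "capture", "date"].tolist()
            disturbances = ev.loc[ev["event_type"] == "disturbance", "date"].tolist()

        filtered: dict[str, BiologgingSeries] = {}
        for var, s in variables.items():
            n_in += len(s)
            fs, _ = windowing.apply_exclusions(s, captures, disturbances)
            n_kept += len(fs)
            filtered[var] = fs
        if "tb" not in filtered or len(filtered["tb"]) == 0:
            log.warnings.append(f"{bear_id}: no Tb data; skipped")
            continue

        smap = segmentation.build_state_map(
            filtered["tb"],
            filtered,
            entry_threshold=config.entry_threshold,
            exit_threshold=config.exit_threshold,
        )
        log.warnings.extend(smap.warnings)
        all_states.append(smap.to_frame())

        for var, s in filtered.items():
            wins, wlog = windowing.tile_windows(
                smap.intervals[var],
                s,
                den_entry=smap.den_entry,
                window_days=config.window_days,
                min_days=config.min_window_days,
                max_gap_days=config.max_gap_days,
            )
            log.warnings.extend(wlog.records)
            window_objects.extend(wins)

    log.record("exclusions", n_in=n_in, n_out=n_kept)

    calls = [
        spectral.classify_window(
            w,
            alpha=config.alpha,
            oversampling=config.oversampling,
            min_period=config.min_period_hours,
            max_period=config.max_period_hours,
        )
        for w in window_objects
    ]
    windows_df = windowing.windows_to_frame(window_objects)
    calls_df = spectral.calls_to_frame(calls)
    log.record("windows", n_windows=len(window_objects))
    log.record("calls", n_calls=len(calls_df))

    den_records = None
    if {"den_lat", "den_lon"} <= set(metadata.columns):
        den_records = pd.DataFrame(
            {
                "bear_id": metadata["bear_id"],
                "date": dt.date(1900, 1, 1),
                "lat": metadata["den_lat"],
                "lon": metadata["den_lon"],
            }
        )
    covariates_df = cov.covariate_table(
        window_objects,
        weather,
        metadata,
        den_records=den_records,
        home_location=(config.latitude, config.longitude),
        k=config.idw_k,
        power=config.idw_power,
    )
    log.record("covariates", n_rows=len(covariates_df))

    merged = covariates_df.merge(calls_df, on="window_id")
    summary = report.period_summary(
        calls_df, windows_df[["window_id", "state", "bear_id", "variable"]]
    )

    results: dict = {
        "states": pd.concat(all_states, ignore_index=True) if all_states else pd.DataFrame(),
        "windows": windows_df,
        "calls": calls_df,
        "covariates": covariates_df,
        "merged": merged,
        "period_summary": summary,
        "log": log,
    }

    if fit_state_model and merged["rhythm_class"].nunique() >= 2:
        spec = rhythm_model.ModelSpec(
            "state", (rhythm_model.Term("state", "categorical"),), groups=("bear_id",)
        )
        tb_rows = merged[merged["variable"] == "tb"]
        if tb_rows["rhythm_class"].nunique() >= 2 and tb_rows["state"].nunique() >= 2:
            model = rhythm_model.fit_multinomial(spec, tb_rows, seed=config.seed)
            results["state_model"] = model
            state_probs = _state_probabilities(model, tb_rows)
            results["state_probabilities"] = state_probs
            log.record("model", loglik=model.loglik, converged=model.converged)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("states", "windows", "calls", "covariates", "merged", "period_summary"):
            results[name].to_csv(out / f"{name}.csv", index=False)
        if "state_probabilities" in results:
            results["state_probabilities"].to_csv(out / "state_probabilities.csv", index=False)
        log.to_json(out / "run_log.json")
    return results


def _state_probabilities(model, data: pd.DataFrame) -> pd.DataFrame:
    """Population-level predicted class probabilities per seasonal state."""
    rows = []
    for state in sorted(data["state"].unique()):
        newdata = pd.DataFrame({"state": [state], "bear_id": ["__population__"]})
        probs = model.predict_probs(newdata).iloc[0]
        rows.append({"state": state, **probs.to_dict()})
    return pd.DataFrame(rows)


def run_simulated_pipeline(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    variables: tuple[str, ...] = ("tb", "hr", "activity"),
) -> tuple[dict, dict[str, GroundTruth]]:
    """Simulate a cohort and push it through the full pipeline."""
    pipe_config = pipe_config or PipelineConfig(seed=sim_config.seed)
    series, truths = simulate_cohort(sim_config, variables=variables)
    weather = simulate_weather(
        sim_config.start_date, sim_config.end_date, n_stations=5, seed=sim_config.seed
    )
    metadata = simulate_metadata(sim_config)
    events = None
    if sim_config.capture_dates or sim_config.disturbance_dates:
        rows = [
            {"bear_id": b, "date": d, "event_type": kind}
            for b in series
            for kind, dates in (
                ("capture", sim_config.capture_dates),
                ("disturbance", sim_config.disturbance_dates),
            )
            for d in dates
        ]
        events = pd.DataFrame(rows)
    results = run_pipeline(series, weather, metadata, pipe_config, out_dir, events)
    return results, truths
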