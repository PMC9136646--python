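"""End-to-end orchestration: simulate/ingest -> QC/label -> metrics -> report.

A run consumes either a synthetic scenario or three existing input files,
applies the QC and filtering cascade, computes the comparison and
exceedance statistics, and writes::

    table1.csv         the three Welch comparison rows
    fig2_counts.csv    per date: houses with any hourly mean >= threshold
    fig3_durations.csv per date: mean hours at or above threshold
    fig4_heatmap.csv   24 x heat-wave-dates matrix of mean indoor temp
    qc_report.csv      per house-day: label, occupancy, completeness, reason
    manifest.json      config hash, seed, version, per-stage counts, summary

Identical config and inputs produce byte-identical outputs.  Any stage
failure aborts with the stage name and removes partial outputs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from heatsense import __version__, heat_metrics, ingestion, qc_labeling
from heatsense.qc_labeling import AC, INDETERMINATE, NONAC, HeatWaveCalendar, build_heatwave_calendar
from heatsense.synthetic_cohort import ScenarioConfig, load_scenario, simulate_cohort

log = logging.getLogger("heatsense")

OUTPUT_FILES = [
    "table1.csv",
    "fig2_counts.csv",
    "fig3_durations.csv",
    "fig4_heatmap.csv",
    "qc_report.csv",
    "manifest.json",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``scenario`` or the three input paths must be supplied.
    """

    out_dir: Path
    scenario: ScenarioConfig | None = None
    telemetry_path: Path | None = None
    metadata_path: Path | None = None
    weather_path: Path | None = None
    calendar: HeatWaveCalendar = field(default_factory=build_heatwave_calendar)
    threshold_c: float = heat_metrics.DEFAULT_THRESHOLD_C
    min_houses: int = qc_labeling.MIN_HOUSES_PER_STATION
    completeness_min_fraction: float = qc_labeling.COMPLETENESS_MIN_FRACTION
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        paths = [self.telemetry_path, self.metadata_path, self.weather_path]
        have_paths = all(p is not None for p in paths)
        if any(p is not None for p in paths) and not have_paths:
            raise ValueError("telemetry, metadata and weather paths must be given together")
        if (self.scenario is None) == (not have_paths):
            raise ValueError("supply exactly one of: a scenario, or the three input paths")
        if not math.isfinite(self.threshold_c):
            raise ValueError("threshold must be finite")

    def canonical_dict(self) -> dict:
        cal = {r: sorted(d.isoformat() for d in days) for r, days in self.calendar.entries.items()}
        out: dict = {
            "threshold_c": self.threshold_c,
            "min_houses": self.min_houses,
            "completeness_min_fraction": self.completeness_min_fraction,
            "calendar": cal,
        }
        if self.scenario is not None:
            s = self.scenario
            out["scenario"] = {
                "n_ac_houses": s.n_ac_houses,
                "n_nonac_houses": s.n_nonac_houses,
                "date_start": s.date_start.isoformat(),
                "date_end": s.date_end.isoformat(),
                "calendar": {
                    r: sorted(d.isoformat() for d in days)
                    for r, days in s.heatwave_calendar.entries.items()
                },
                "group_daytype_mean": {f"{g}/{d}": v for (g, d), v in sorted(s.group_daytype_mean.items())},
                "diurnal_amplitude": {f"{g}/{d}": v for (g, d), v in sorted(s.diurnal_amplitude.items())},
                "peak_hour": s.peak_hour,
                "house_effect_sd": s.house_effect_sd,
                "sample_noise_sd": s.sample_noise_sd,
                "away_day_prob": s.away_day_prob,
                "missing_day_prob": s.missing_day_prob,
                "outdoor": [s.outdoor_base, s.outdoor_amplitude, s.outdoor_heatwave_boost, s.outdoor_noise_sd],
                "rng_seed": s.rng_seed,
            }
        else:
            out["inputs"] = {
                "telemetry": str(self.telemetry_path),
                "metadata": str(self.metadata_path),
                "weather": str(self.weather_path),
            }
        return out


def _fmt(v: float, digits: int = 6) -> str:
    return "" if pd.isna(v) else f"{v:.{digits}g}"


def _write_table1(comparisons: list[heat_metrics.GroupComparison], path: Path) -> None:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "group_a": c.group_a_name,
                "group_b": c.group_b_name,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": _fmt(c.mean_a),
                "mean_b": _fmt(c.mean_b),
                "mean_difference": _fmt(c.mean_difference),
                "t_statistic": _fmt(c.t_statistic),
                "welch_df": _fmt(c.welch_df),
                "p_one_tailed": _fmt(c.p_one_tailed, 3),
                "ci99_lower": _fmt(c.ci_99[0]),
                "ci99_upper": _fmt(c.ci_99[1]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def _build_house_days(
    telemetry: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-house-day QC table: flags, label, hourly/daily means."""
    ts = telemetry["timestamp"]
    t = telemetry.assign(
        date=ts.dt.date,
        hour=ts.dt.hour,
        stage_pos=telemetry["cooling_stage"] > 0,
        mode_cool=telemetry["hvac_mode"] == "cool",
    )
    flags = t.groupby(["house_id", "date"], sort=True, observed=True).agg(
        n_samples=("indoor_temp_c", "size"),
        n_hours=("hour", "nunique"),
        occupied=("motion", "max"),
        any_stage=("stage_pos", "max"),
        any_cool_telemetry=("mode_cool", "max"),
    ).reset_index()

    meta = metadata.set_index("house_id")
    flags = flags.join(
        meta[["region", "configured_hvac_mode"]], on="house_id", how="left"
    )
    flags["cool_recorded"] = flags["any_cool_telemetry"] | (
        flags["configured_hvac_mode"] == "cool"
    )
    flags["complete"] = (
        flags["n_samples"] >= config.completeness_min_fraction * qc_labeling.EXPECTED_SAMPLES_PER_DAY
    ) & (flags["n_hours"] == 24)
    flags["occupied"] = flags["occupied"].astype(bool)
    flags["ac_label"] = qc_labeling.label_days(flags)

    daily = heat_metrics.daily_means_table(heat_metrics.hourly_means_table(telemetry))
    flags = flags.merge(daily, on=["house_id", "date"], how="left")
    flags["is_heatwave_day"] = [
        config.calendar.is_heatwave(r, d) if isinstance(r, str) else False
        for r, d in zip(flags["region"], flags["date"])
    ]
    return flags


def _exclusion_reason(row: pd.Series) -> str:
    if not row["complete"]:
        return "incomplete"
    if not row["occupied"]:
        return "unoccupied"
    if row["ac_label"] == INDETERMINATE:
        return "indeterminate label"
    return ""


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except StageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    counts: dict[str, int] = {}

    stage = "simulate"
    try:
        if config.scenario is not None:
            paths = simulate_cohort(config.scenario, out_dir / "inputs")
            telemetry_path, metadata_path, weather_path = (
                paths["telemetry"], paths["metadata"], paths["weather"],
            )
        else:
            telemetry_path, metadata_path, weather_path = (
                config.telemetry_path, config.metadata_path, config.weather_path,
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "ingest"
    try:
        telemetry, telemetry_report = ingestion.read_telemetry(telemetry_path)
        metadata, metadata_report = ingestion.read_metadata(metadata_path)
        weather, weather_report = ingestion.read_weather(weather_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    counts["telemetry_rows"] = telemetry_report.rows_parsed
    counts["telemetry_rows_rejected"] = telemetry_report.rows_rejected
    counts["houses_in_metadata"] = len(metadata)
    log.info("ingested %d telemetry rows (%d rejected), %d houses",
             telemetry_report.rows_parsed, telemetry_report.rows_rejected, len(metadata))

    stage = "qc_label"
    try:
        house_days = _build_house_days(telemetry, metadata, config)
        house_days["reason"] = house_days.apply(_exclusion_reason, axis=1)
        qc_report = house_days[
            ["house_id", "date", "ac_label", "occupied", "complete", "reason"]
        ].copy()
        qc_path = out_dir / "qc_report.csv"
        qc_report.to_csv(qc_path, index=False, lineterminator="\n")
        written.append(qc_path)
        retained = house_days[house_days["reason"] == ""].copy()
    except Exception as exc:
        raise StageError(stage, exc) from exc
    counts["house_days_observed"] = len(house_days)
    counts["house_days_incomplete"] = int((house_days["reason"] == "incomplete").sum())
    counts["house_days_unoccupied"] = int((house_days["reason"] == "unoccupied").sum())
    counts["house_days_indeterminate"] = int((house_days["reason"] == "indeterminate label").sum())
    counts["house_days_after_qc"] = len(retained)

    stage = "map_stations"
    try:
        stations = (
            weather.groupby("station_id", sort=True)
            .agg(latitude=("latitude", "first"), longitude=("longitude", "first"))
            .reset_index()
        )
        assigned, unassigned = qc_labeling.assign_stations(metadata, stations)
        station_of = dict(zip(metadata["house_id"], assigned))
        retained["station_id"] = retained["house_id"].map(station_of)
        retained = retained[retained["station_id"].notna()]
        counts["houses_unassigned_station"] = len(unassigned)
        before = len(retained)
        retained = qc_labeling.filter_station_coverage(retained, config.min_houses)
        counts["house_days_dropped_station_coverage"] = before - len(retained)
        before = len(retained)
        retained = retained[retained["region"].isin(config.calendar.regions)]
        counts["house_days_dropped_region"] = before - len(retained)
        counts["house_days_analysed"] = len(retained)
        counts["houses_analysed"] = retained["house_id"].nunique()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "metrics"
    try:
        comparisons = [
            heat_metrics.compare_ac_vs_nonac(retained, "HW"),
            heat_metrics.compare_ac_vs_nonac(retained, "NHW"),
            heat_metrics.compare_hw_vs_nonhw_nonac(retained),
        ]
        table1_path = out_dir / "table1.csv"
        _write_table1(comparisons, table1_path)
        written.append(table1_path)

        season_houses = qc_labeling.season_nonac_households(house_days, config.calendar)
        season_houses &= set(retained["house_id"])
        season_days = retained[
            (retained["house_id"].isin(season_houses)) & (retained["ac_label"] == NONAC)
        ]
        counts["season_nonac_houses"] = len(season_houses)

        hourly = heat_metrics.hourly_means_table(telemetry)
        keys = set(zip(season_days["house_id"], season_days["date"]))
        mask = [k in keys for k in zip(hourly["house_id"], hourly["date"])]
        season_hourly = hourly[np.asarray(mask, bool)]

        records = heat_metrics.exceedance_by_date(season_hourly, config.threshold_c)
        fig2 = pd.DataFrame(
            {"date": [r.date.isoformat() for r in records],
             "n_houses_at_or_above": [r.n_houses_at_or_above for r in records]}
        )
        fig3 = pd.DataFrame(
            {"date": [r.date.isoformat() for r in records],
             "mean_duration_hours": [_fmt(r.mean_duration_hours) for r in records]}
        )
        fig2_path, fig3_path = out_dir / "fig2_counts.csv", out_dir / "fig3_durations.csv"
        fig2.to_csv(fig2_path, index=False, lineterminator="\n")
        fig3.to_csv(fig3_path, index=False, lineterminator="\n")
        written += [fig2_path, fig3_path]

        hw_dates = sorted(config.calendar.all_dates)
        matrix = heat_metrics.hourly_heatmap(season_hourly, hw_dates)
        heatmap = pd.DataFrame(
            matrix.values, index=pd.Index(range(24), name="hour"),
            columns=[d.isoformat() for d in matrix.dates],
        )
        fig4_path = out_dir / "fig4_heatmap.csv"
        heatmap.to_csv(fig4_path, float_format="%.4f", lineterminator="\n")
        written.append(fig4_path)

        # pooled exceedance duration on heat-wave house-days (region-aware)
        hw_season = season_days[season_days["is_heatwave_day"]]
        hw_keys = set(zip(hw_season["house_id"], hw_season["date"]))
        durations = [
            dur
            for r in records
            for house, dur in r.per_house_durations.items()
            if (house, r.date) in hw_keys
        ]
        mean_hw_duration = float(np.mean(durations)) if durations else float("nan")

        window = (
            heat_metrics.hottest_window(matrix)
            if not np.isnan(matrix.values).all()
            else None
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "manifest"
    try:
        summary = {
            "comparisons": [
                {
                    "groups": f"{c.group_a_name} vs {c.group_b_name}",
                    "n_a": c.n_a, "n_b": c.n_b,
                    "mean_a": round(c.mean_a, 4), "mean_b": round(c.mean_b, 4),
                    "mean_difference": round(c.mean_difference, 4),
                    "t": round(c.t_statistic, 3), "df": round(c.welch_df, 1),
                    "p_one_tailed": float(f"{c.p_one_tailed:.3g}"),
                    "ci_99": [round(c.ci_99[0], 4), round(c.ci_99[1], 4)],
                }
                for c in comparisons
            ],
            "threshold_c": config.threshold_c,
            "mean_heatwave_exceedance_hours": (
                None if math.isnan(mean_hw_duration) else round(mean_hw_duration, 3)
            ),
            "n_heatwave_house_days": len(hw_season),
            "hottest_window": list(window) if window else None,
        }
        manifest = {
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(config.canonical_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.scenario.rng_seed if config.scenario else None,
            "stage_counts": counts,
            "outputs": sorted(str(p.name) for p in written) + ["manifest.json"],
            "summary": summary,
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return manifest


def summarize(manifest: dict) -> str:
    """Human-readable report of a completed run."""
    lines = [f"heatsense run (v{manifest['version']}, config {manifest['config_hash'][:12]})"]
    counts = manifest["stage_counts"]
    lines.append(
        f"  houses: {counts.get('houses_in_metadata', '?')} in metadata -> "
        f"{counts.get('houses_analysed', '?')} analysed; "
        f"house-days: {counts.get('house_days_observed', '?')} -> "
        f"{counts.get('house_days_analysed', '?')}"
    )
    summary = manifest["summary"]
    for c in summary["comparisons"]:
        lines.append(
            f"  {c['groups']}: diff {c['mean_difference']:+.3f} degC "
            f"(means {c['mean_a']:.3f} vs {c['mean_b']:.3f}, n={c['n_a']}/{c['n_b']}, "
            f"t={c['t']:.2f}, df={c['df']:.0f}, one-tailed p={c['p_one_tailed']:.3g}, "
            f"99% CI [{c['ci_99'][0]:.3f}, {c['ci_99'][1]:.3f}])"
        )
    dur = summary["mean_heatwave_exceedance_hours"]
    if dur is None:
        lines.append(f"  no non-AC season subset: exceedance at {summary['threshold_c']:g} degC not computed")
    else:
        lines.append(
            f"  mean time at or above {summary['threshold_c']:g} degC on heat-wave days: "
            f"{dur:.2f} h over {summary['n_heatwave_house_days']} non-AC house-days"
        )
    if summary["hottest_window"]:
        h0, h1 = summary["hottest_window"]
        lines.append(f"  hottest indoor hours on heat-wave days: {h0:02d}:00-{h1:02d}:00")
    return "\n".join(lines)


def load_run_config(path: str | Path, out_dir: str | Path | None = None,
                    seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a TOML file (CLI entry point).

    The file supplies either ``scenario = "scenario.toml"`` (or an inline
    ``[scenario]`` table) or an ``[inputs]`` table with the three paths;
    plus optional ``[params]`` and ``[[calendar]]`` sections.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    base = path.parent

    scenario = None
    tele = meta = wx = None
    if "scenario" in doc and isinstance(doc["scenario"], str):
        scenario = load_scenario(base / doc["scenario"])
    elif "inputs" in doc:
        inputs = doc["inputs"]
        tele = base / inputs["telemetry"]
        meta = base / inputs["metadata"]
        wx = base / inputs["weather"]
    elif {"cohort", "means", "amplitudes", "outdoor", "calendar"} & doc.keys():
        scenario = load_scenario(path)  # whole file is a scenario
    else:
        raise ValueError(f"{path}: config defines neither [inputs] nor a scenario")
    if seed is not None and scenario is not None:
        from dataclasses import replace
        scenario = replace(scenario, rng_seed=seed)

    params = doc.get("params", {})
    calendar = build_heatwave_calendar(
        [
            (e["region"], _as_date(e["start"]), _as_date(e["end"]))
            for e in doc["calendar"]
        ]
        if "calendar" in doc
        else None
    )
    return RunConfig(
        out_dir=Path(out_dir) if out_dir else base / doc.get("out_dir", "heatsense_out"),
        scenario=scenario,
        telemetry_path=tele,
        metadata_path=meta,
        weather_path=wx,
        calendar=calendar,
        threshold_c=params.get("threshold_c", heat_metrics.DEFAULT_THRESHOLD_C),
        min_houses=params.get("min_houses", qc_labeling.MIN_HOUSES_PER_STATION),
        completeness_min_fraction=params.get(
            "completeness_min_fraction", qc_labeling.COMPLETENESS_MIN_FRACTION
        ),
    )


def _as_date(v) -> dt.date:
    return v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))
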