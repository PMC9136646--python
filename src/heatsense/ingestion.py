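"""Readers and writers for the three CSV interchange dialects.

All files are UTF-8, comma-delimited, with a mandatory header row and
ISO-8601 minute-resolution timestamps (``YYYY-MM-DDTHH:MM``, naive local
standard time).  Temperatures are degrees Celsius throughout.

Telemetry dialect
    ``house_id, timestamp, indoor_temp_c, cooling_stage, hvac_mode, motion``
    -- one row per 5-minute thermostat sample.  ``cooling_stage`` is the
    integer 0-4 compressor stage (0 = no cooling), ``hvac_mode`` one of
    cool/heat/auto/off, ``motion`` 0/1 (also accepts true/false).

Metadata dialect
    ``house_id, city, region, latitude, longitude, n_sensors,
    configured_hvac_mode, station_id`` -- one row per house.  Coordinates
    and ``station_id`` may be blank, but a house needs at least one basis
    for weather-station assignment (coordinates, a pre-assigned station, or
    a city present in a lookup).

Weather dialect (Environment-Canada-hourly style)
    ``Station ID, Station Name, Latitude, Longitude, Date/Time (LST),
    Temp (°C)`` -- one row per station-hour; a blank temperature cell is a
    missing observation, never zero.

Readers never silently drop data: every input row is either parsed or
rejected with a reason, and ``rows_in == rows_parsed + rows_rejected``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TELEMETRY_COLUMNS = [
    "house_id",
    "timestamp",
    "indoor_temp_c",
    "cooling_stage",
    "hvac_mode",
    "motion",
]
METADATA_COLUMNS = [
    "house_id",
    "city",
    "region",
    "latitude",
    "longitude",
    "n_sensors",
    "configured_hvac_mode",
    "station_id",
]
WEATHER_COLUMNS = [
    "Station ID",
    "Station Name",
    "Latitude",
    "Longitude",
    "Date/Time (LST)",
    "Temp (°C)",
]

HVAC_MODES = frozenset({"cool", "heat", "auto", "off"})
COOLING_STAGES = frozenset({0, 1, 2, 3, 4})
INDOOR_TEMP_BOUNDS = (-10.0, 60.0)
OUTDOOR_TEMP_BOUNDS = (-60.0, 60.0)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


@dataclass(frozen=True)
class ThermostatSample:
    """One 5-minute telemetry record."""

    house_id: str
    timestamp: pd.Timestamp
    indoor_temp_c: float
    cooling_stage: int
    hvac_mode: str
    motion: bool


@dataclass(frozen=True)
class HouseMetadata:
    """Static description of one house."""

    house_id: str
    city: str
    region: str
    latitude: float | None
    longitude: float | None
    n_sensors: int
    configured_hvac_mode: str
    station_id: str | None = None


@dataclass(frozen=True)
class WeatherObservation:
    """One hourly outdoor-temperature observation at a station."""

    station_id: str
    station_name: str
    latitude: float
    longitude: float
    timestamp: pd.Timestamp
    outdoor_temp_c: float | None


@dataclass
class ReadReport:
    """Row-level accounting for one file read."""

    path: str
    rows_in: int = 0
    rows_parsed: int = 0
    rows_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    example_rows: dict[str, list[int]] = field(default_factory=dict)

    def reject(self, mask: pd.Series | np.ndarray, reason: str) -> None:
        n = int(np.asarray(mask).sum())
        if n == 0:
            return
        self.reasons[reason] = self.reasons.get(reason, 0) + n
        idx = np.flatnonzero(np.asarray(mask))[:5]
        self.example_rows.setdefault(reason, []).extend(int(i) for i in idx)


class DialectError(ValueError):
    """Header or schema violation that makes a file unreadable."""


def _require_columns(frame: pd.DataFrame, required: list[str], path: Path) -> None:
    for col in required:
        if col not in frame.columns:
            raise DialectError(f"{path}: missing required column {col!r}")


def _normalise_timestamps(raw: pd.Series, resolution_min: int) -> pd.Series:
    ts = pd.to_datetime(raw, format=TIMESTAMP_FORMAT, errors="coerce")
    return ts.dt.round(f"{resolution_min}min")


def read_telemetry(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read the telemetry dialect, validating every row.

    Returns the parsed samples (one row per retained sample, timestamps
    normalised to the 5-minute grid, keep-first deduplication on
    ``(house_id, timestamp)``) together with a :class:`ReadReport`.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, TELEMETRY_COLUMNS, path)
    report = ReadReport(path=str(path), rows_in=len(raw))

    ts = _normalise_timestamps(raw["timestamp"], 5)
    temp = pd.to_numeric(raw["indoor_temp_c"], errors="coerce")
    stage = pd.to_numeric(raw["cooling_stage"], errors="coerce")
    mode = raw["hvac_mode"].str.strip().str.lower()
    motion = (
        raw["motion"]
        .str.strip()
        .str.lower()
        .map({"0": False, "1": True, "false": False, "true": True})
    )

    bad = pd.Series(False, index=raw.index)
    for mask, reason in [
        (ts.isna(), "unparseable timestamp"),
        (temp.isna() | (temp < INDOOR_TEMP_BOUNDS[0]) | (temp > INDOOR_TEMP_BOUNDS[1]),
         "indoor temperature missing or outside validation bounds"),
        (stage.isna() | ~stage.isin(list(COOLING_STAGES)), "invalid cooling_stage"),
        (~mode.isin(list(HVAC_MODES)), "invalid hvac_mode"),
        (motion.isna(), "invalid motion flag"),
    ]:
        mask = mask & ~bad
        report.reject(mask, reason)
        bad |= mask

    frame = pd.DataFrame(
        {
            "house_id": raw["house_id"],
            "timestamp": ts,
            "indoor_temp_c": temp,
            "cooling_stage": stage,
            "hvac_mode": mode,
            "motion": motion,
        }
    )[~bad]

    dup = frame.duplicated(subset=["house_id", "timestamp"], keep="first")
    report.reject(dup.reindex(raw.index, fill_value=False), "duplicate (house_id, timestamp), keep-first")
    frame = frame[~dup]

    frame = frame.astype(
        {"cooling_stage": np.int8, "motion": bool, "indoor_temp_c": float}
    ).reset_index(drop=True)
    report.rows_parsed = len(frame)
    report.rows_rejected = report.rows_in - report.rows_parsed
    return frame, report


def read_metadata(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read the house-metadata dialect (one record per house).

    A duplicated ``house_id`` is a hard failure; a record with no
    coordinates, no pre-assigned station and no city is rejected because it
    could never be mapped to a weather station.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, METADATA_COLUMNS, path)
    report = ReadReport(path=str(path), rows_in=len(raw))
    if raw.empty:
        warnings.warn(f"{path}: metadata file is empty", stacklevel=2)

    dup = raw["house_id"].duplicated(keep=False)
    if dup.any():
        raise DialectError(
            f"{path}: duplicate house_id values: "
            f"{sorted(raw.loc[dup, 'house_id'].unique())[:5]}"
        )

    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    lon = pd.to_numeric(raw["longitude"], errors="coerce")
    n_sensors = pd.to_numeric(raw["n_sensors"], errors="coerce")
    has_coords = lat.notna() & lon.notna()
    has_station = raw["station_id"].str.strip() != ""
    has_city = raw["city"].str.strip() != ""

    bad = pd.Series(False, index=raw.index)
    for mask, reason in [
        (n_sensors.isna() | (n_sensors < 1), "n_sensors missing or < 1"),
        (~(has_coords | has_station | has_city), "no basis for station assignment"),
    ]:
        mask = mask & ~bad
        report.reject(mask, reason)
        bad |= mask

    frame = pd.DataFrame(
        {
            "house_id": raw["house_id"],
            "city": raw["city"].str.strip(),
            "region": raw["region"].str.strip(),
            "latitude": lat,
            "longitude": lon,
            "n_sensors": n_sensors,
            "configured_hvac_mode": raw["configured_hvac_mode"].str.strip().str.lower(),
            "station_id": raw["station_id"].str.strip().replace("", pd.NA),
        }
    )[~bad]
    frame = frame.astype({"n_sensors": int}).reset_index(drop=True)
    report.rows_parsed = len(frame)
    report.rows_rejected = report.rows_in - report.rows_parsed
    return frame, report


def read_weather(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read the Environment-Canada-hourly-style weather dialect.

    Blank temperature cells become missing values (NaN).  Non-hourly
    spacing within a station triggers a warning with a gap report but the
    rows are kept.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, WEATHER_COLUMNS, path)
    report = ReadReport(path=str(path), rows_in=len(raw))

    ts = _normalise_timestamps(raw["Date/Time (LST)"], 60)
    temp_raw = raw["Temp (°C)"].str.strip()
    temp = pd.to_numeric(temp_raw.replace("", pd.NA), errors="coerce")
    out_of_bounds = temp.notna() & (
        (temp < OUTDOOR_TEMP_BOUNDS[0]) | (temp > OUTDOOR_TEMP_BOUNDS[1])
    )
    unparseable = (temp_raw != "") & temp.isna()

    bad = pd.Series(False, index=raw.index)
    for mask, reason in [
        (ts.isna(), "unparseable timestamp"),
        (unparseable | out_of_bounds, "temperature unparseable or outside validation bounds"),
    ]:
        mask = mask & ~bad
        report.reject(mask, reason)
        bad |= mask

    frame = pd.DataFrame(
        {
            "station_id": raw["Station ID"],
            "station_name": raw["Station Name"],
            "latitude": pd.to_numeric(raw["Latitude"], errors="coerce"),
            "longitude": pd.to_numeric(raw["Longitude"], errors="coerce"),
            "timestamp": ts,
            "outdoor_temp_c": temp,
        }
    )[~bad].reset_index(drop=True)

    gaps = 0
    for _, obs in frame.groupby("station_id", sort=False):
        deltas = obs["timestamp"].sort_values().diff().dropna()
        gaps += int((deltas != pd.Timedelta(hours=1)).sum())
    if gaps:
        warnings.warn(f"{path}: {gaps} non-hourly gaps between observations", stacklevel=2)

    report.rows_parsed = len(frame)
    report.rows_rejected = report.rows_in - report.rows_parsed
    return frame, report


def _format_timestamps(ts: pd.Series) -> np.ndarray:
    # minute-resolution datetime64 renders exactly as YYYY-MM-DDTHH:MM
    return ts.to_numpy().astype("datetime64[m]").astype(str)


def write_telemetry(frame: pd.DataFrame, path: str | Path) -> None:
    """Write samples in the telemetry dialect (motion encoded 0/1)."""
    out = pd.DataFrame(
        {
            "house_id": frame["house_id"],
            "timestamp": _format_timestamps(frame["timestamp"]),
            "indoor_temp_c": frame["indoor_temp_c"].astype(float),
            "cooling_stage": frame["cooling_stage"].astype(int),
            "hvac_mode": frame["hvac_mode"],
            "motion": frame["motion"].astype(int),
        }
    )
    out.to_csv(path, index=False, float_format="%.3f", lineterminator="\n")


def write_metadata(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    for col in ("latitude", "longitude"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.5f}")
    out["station_id"] = out["station_id"].fillna("")
    out[METADATA_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def write_weather(frame: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Station ID": frame["station_id"],
            "Station Name": frame["station_name"],
            "Latitude": frame["latitude"].map("{:.5f}".format),
            "Longitude": frame["longitude"].map("{:.5f}".format),
            "Date/Time (LST)": _format_timestamps(frame["timestamp"]),
            "Temp (°C)": frame["outdoor_temp_c"].map(
                lambda v: "" if pd.isna(v) else f"{v:.2f}"
            ),
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")
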