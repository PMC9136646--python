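"""QC, labeling and filtering of house-days.

Implements the study's filtering procedure on 5-minute telemetry grouped
into house-days (one dwelling, one calendar date, midnight-to-midnight
local standard time):

* per-day air-conditioning label from cooling-stage activity and the HVAC
  mode (telemetry or configured metadata mode);
* occupancy from motion-sensor activation (any motion in the day);
* completeness screening (at least 80% of the 288 expected samples and
  every hour bin represented);
* nearest-weather-station assignment by great-circle distance;
* a station-coverage filter (stations need at least 30 distinct houses);
* the official heat-wave calendar (region -> date set);
* the season-level non-AC household subset used by the exceedance
  analysis.

The AC rule is a conjunction of two signals: a day is labeled AC only if a
nonzero cooling stage was observed AND "cool" appears as the HVAC mode
(at any point in the day's telemetry, or as the configured metadata mode);
it is labeled non-AC only if the cooling stage was 0 all day AND "cool"
appears in neither source.  Days matching neither rule (e.g. nonzero stage
but "cool" never recorded) are labeled INDETERMINATE and excluded
downstream rather than force-assigned to either group.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AC = "AC"
NONAC = "NONAC"
INDETERMINATE = "INDETERMINATE"

EXPECTED_SAMPLES_PER_DAY = 288
COMPLETENESS_MIN_FRACTION = 0.8
MIN_HOUSES_PER_STATION = 30

#: Official 2018 heat-wave declarations: the 6-day June 30 - July 5 event
#: for the greater Montreal and Outaouais health regions, plus the
#: August 4 single-day event declared for Outaouais only.
DEFAULT_REGION_SPECS: list[tuple[str, dt.date, dt.date]] = [
    ("Montréal", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Laval", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Montérégie", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Outaouais", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Outaouais", dt.date(2018, 8, 4), dt.date(2018, 8, 4)),
]


@dataclass(frozen=True)
class HeatWaveCalendar:
    """Region -> set of official heat-wave dates."""

    entries: dict[str, frozenset[dt.date]] = field(default_factory=dict)

    def dates_for(self, region: str) -> frozenset[dt.date]:
        return self.entries.get(region, frozenset())

    def is_heatwave(self, region: str, date: dt.date) -> bool:
        return date in self.dates_for(region)

    @property
    def regions(self) -> frozenset[str]:
        return frozenset(self.entries)

    @property
    def all_dates(self) -> frozenset[dt.date]:
        out: set[dt.date] = set()
        for dates in self.entries.values():
            out |= dates
        return frozenset(out)


def build_heatwave_calendar(
    region_specs: list[tuple[str, dt.date, dt.date]] | None = None,
) -> HeatWaveCalendar:
    """Expand (region, start, end) inclusive ranges into a calendar.

    With no argument, builds the default 2018 calendar
    (:data:`DEFAULT_REGION_SPECS`).  Raises ``ValueError`` if a range ends
    before it starts.
    """
    specs = DEFAULT_REGION_SPECS if region_specs is None else region_specs
    entries: dict[str, set[dt.date]] = {}
    for region, start, end in specs:
        if end < start:
            raise ValueError(f"{region}: range end {end} before start {start}")
        days = {start + dt.timedelta(days=i) for i in range((end - start).days + 1)}
        entries.setdefault(region, set()).update(days)
    return HeatWaveCalendar({r: frozenset(d) for r, d in entries.items()})


def label_ac_day(samples: pd.DataFrame, configured_hvac_mode: str = "") -> str:
    """Label one house-day AC / NONAC / INDETERMINATE.

    ``samples`` must hold the telemetry of a single house on a single date
    (columns ``cooling_stage`` and ``hvac_mode``).
    """
    if samples.empty:
        raise ValueError("cannot label an empty house-day")
    any_stage = bool((samples["cooling_stage"] > 0).any())
    cool_recorded = bool((samples["hvac_mode"] == "cool").any()) or (
        configured_hvac_mode == "cool"
    )
    return _label(any_stage, cool_recorded)


def _label(any_stage: bool, cool_recorded: bool) -> str:
    if any_stage and cool_recorded:
        return AC
    if not any_stage and not cool_recorded:
        return NONAC
    return INDETERMINATE


def label_days(day_flags: pd.DataFrame) -> pd.Series:
    """Vectorised labeling from per-house-day flags.

    ``day_flags`` needs boolean columns ``any_stage`` (any nonzero cooling
    stage that day) and ``cool_recorded`` ("cool" seen in telemetry mode or
    the configured metadata mode).
    """
    out = pd.Series(INDETERMINATE, index=day_flags.index, dtype=object)
    out[day_flags["any_stage"] & day_flags["cool_recorded"]] = AC
    out[~day_flags["any_stage"] & ~day_flags["cool_recorded"]] = NONAC
    return out


def detect_occupancy(samples: pd.DataFrame) -> bool:
    """A house-day is occupied iff at least one sample has motion."""
    return bool(samples["motion"].any())


def assess_completeness(
    samples: pd.DataFrame,
    expected: int = EXPECTED_SAMPLES_PER_DAY,
    min_fraction: float = COMPLETENESS_MIN_FRACTION,
) -> tuple[bool, float]:
    """Completeness check for one house-day.

    Complete iff at least ``min_fraction`` of the ``expected`` 5-minute
    samples are present AND every one of the 24 hour bins has at least one
    sample.  Returns ``(complete, n_samples / expected)``.
    """
    fraction = len(samples) / expected
    if samples.empty:
        return False, 0.0
    hours_covered = samples["timestamp"].dt.hour.nunique()
    return (fraction >= min_fraction) and (hours_covered == 24), fraction


_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def assign_station(
    house: pd.Series,
    stations: pd.DataFrame,
    city_to_station: dict[str, str] | None = None,
) -> str | None:
    """Weather station for one house, or ``None`` if no basis exists.

    A pre-assigned ``station_id`` wins; otherwise the great-circle nearest
    station (ties broken toward the lexicographically smallest station id);
    otherwise a city -> station lookup.  ``stations`` needs columns
    ``station_id, latitude, longitude``.
    """
    pre = house.get("station_id")
    if isinstance(pre, str) and pre:
        return pre
    lat, lon = house.get("latitude"), house.get("longitude")
    if pd.notna(lat) and pd.notna(lon):
        ordered = stations.sort_values("station_id").reset_index(drop=True)
        d = haversine_km(lat, lon, ordered["latitude"].to_numpy(), ordered["longitude"].to_numpy())
        return str(ordered.loc[int(np.argmin(d)), "station_id"])  # argmin keeps first = smallest id
    city = house.get("city")
    if city_to_station and isinstance(city, str) and city in city_to_station:
        return city_to_station[city]
    return None


def assign_stations(
    metadata: pd.DataFrame,
    stations: pd.DataFrame,
    city_to_station: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.Index]:
    """Station id per house; also returns the houses with no basis."""
    assigned = metadata.apply(assign_station, axis=1, stations=stations, city_to_station=city_to_station)
    assigned.name = "station_id"
    unassigned = metadata.index[assigned.isna()]
    return assigned, unassigned


def filter_station_coverage(
    house_days: pd.DataFrame, min_houses: int = MIN_HOUSES_PER_STATION
) -> pd.DataFrame:
    """Keep house-days whose station has >= min_houses distinct houses."""
    if house_days.empty:
        return house_days
    counts = house_days.groupby("station_id")["house_id"].nunique()
    keep = counts.index[counts >= min_houses]
    return house_days[house_days["station_id"].isin(keep)]


def season_nonac_households(
    house_days: pd.DataFrame, calendar: HeatWaveCalendar
) -> set[str]:
    """Houses eligible for the season-level non-AC exceedance analysis.

    A house qualifies iff it lies in a region with a declared heat wave,
    none of its labeled days in the window is AC, and it was occupied on at
    least one official heat-wave date in its region (a house away for the
    whole event may simply have switched its AC off).  ``house_days``
    needs columns ``house_id, date, region, ac_label, occupied``.
    """
    if house_days.empty:
        return set()
    in_region = house_days[house_days["region"].isin(calendar.regions)]
    used_ac = set(in_region.loc[in_region["ac_label"] == AC, "house_id"])
    is_hw = [
        calendar.is_heatwave(r, d)
        for r, d in zip(in_region["region"], in_region["date"])
    ]
    hw_days = in_region[np.asarray(is_hw, bool)]
    occupied_hw = set(hw_days.loc[hw_days["occupied"], "house_id"])
    return (occupied_hw - used_ac)
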