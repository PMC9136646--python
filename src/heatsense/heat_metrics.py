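"""Study statistics on QC'd house-days.

Aggregation is hierarchical: 5-minute samples -> hourly means (half-open
hour bins [h, h+1)) -> daily mean (mean of the non-missing hourly means)
-> pooled house-day groups.  The unit of analysis is the house-day,
pooled across houses with no within-house correlation adjustment.

Group comparisons use the one-tailed Welch t test (unequal variances,
Welch-Satterthwaite degrees of freedom), reported together with the
two-sided 99% confidence interval of the mean difference.  The one-tailed
directions are fixed by the phenomenon: air-conditioned houses cooler than
non-air-conditioned, heat-wave days hotter than other days.

Threshold exceedance is computed on hourly means: a house-day's duration
is the number of hour bins whose mean is at or above the threshold
(26 degC by default, the ASHRAE 55 safe-indoor-temperature bound), and a
house counts toward a date's exceedance tally iff its duration that day is
positive.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from heatsense.qc_labeling import AC, NONAC, HeatWaveCalendar

DEFAULT_THRESHOLD_C = 26.0


@dataclass(frozen=True)
class GroupComparison:
    """One comparison row: Welch t on pooled house-day daily means."""

    group_a_name: str
    group_b_name: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float  # a - b
    t_statistic: float
    welch_df: float
    p_one_tailed: float
    ci_99: tuple[float, float]


@dataclass(frozen=True)
class ExceedanceRecord:
    """Per-date threshold exceedance among contributing houses."""

    date: dt.date
    n_houses_at_or_above: int
    mean_duration_hours: float
    per_house_durations: dict[str, int]


@dataclass(frozen=True)
class HeatmapMatrix:
    """Hour-by-date mean indoor temperature (24 x len(dates)); NaN = missing."""

    dates: list[dt.date]
    values: np.ndarray  # shape (24, n_dates)


def hourly_means(samples: pd.DataFrame) -> np.ndarray:
    """24 hourly means for one house-day; NaN where an hour has no samples."""
    out = np.full(24, np.nan)
    if samples.empty:
        return out
    grouped = samples.groupby(samples["timestamp"].dt.hour)["indoor_temp_c"].mean()
    out[grouped.index.to_numpy()] = grouped.to_numpy()
    return out


def daily_mean(hourly: np.ndarray) -> float:
    """Mean of non-missing hourly means; NaN when all 24 are missing."""
    hourly = np.asarray(hourly, float)
    if np.isnan(hourly).all():
        return float("nan")
    return float(np.nanmean(hourly))


def hourly_means_table(telemetry: pd.DataFrame) -> pd.DataFrame:
    """Long table of hourly means: columns house_id, date, hour, temp."""
    ts = telemetry["timestamp"]
    out = (
        telemetry.assign(date=ts.dt.date, hour=ts.dt.hour)
        .groupby(["house_id", "date", "hour"], sort=True, observed=True)["indoor_temp_c"]
        .mean()
        .rename("temp")
        .reset_index()
    )
    return out


def daily_means_table(hourly: pd.DataFrame) -> pd.DataFrame:
    """Daily mean per house-day from the hourly long table."""
    return (
        hourly.groupby(["house_id", "date"], sort=True, observed=True)["temp"]
        .mean()
        .rename("daily_mean")
        .reset_index()
    )


def welch_one_tailed(
    values_a,
    values_b,
    alternative: str,
    ci_level: float = 0.99,
    group_a_name: str = "a",
    group_b_name: str = "b",
) -> GroupComparison:
    """Welch t test with a one-tailed p and a two-sided CI of the difference.

    ``alternative`` is ``"a_less"`` (H1: mean_a < mean_b) or
    ``"a_greater"``.  Requires n >= 2 per group and a nonzero variance in
    at least one group.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    for name, x in ((group_a_name, a), (group_b_name, b)):
        if x.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values, got {x.size}")
        if not np.isfinite(x).all():
            raise ValueError(f"group {name!r} contains non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError(
            f"both groups ({group_a_name!r}, {group_b_name!r}) have zero variance"
        )
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if alternative == "a_less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "a_greater":
        p = float(stats.t.sf(t, df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    half = float(stats.t.ppf(0.5 + ci_level / 2, df)) * np.sqrt(se2)
    return GroupComparison(
        group_a_name=group_a_name,
        group_b_name=group_b_name,
        n_a=int(na),
        n_b=int(nb),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(diff),
        t_statistic=float(t),
        welch_df=float(df),
        p_one_tailed=p,
        ci_99=(float(diff - half), float(diff + half)),
    )


def _ensure_heatwave_flag(
    house_days: pd.DataFrame, calendar: HeatWaveCalendar | None
) -> pd.Series:
    if "is_heatwave_day" in house_days.columns:
        return house_days["is_heatwave_day"].astype(bool)
    if calendar is None:
        raise ValueError("need either an is_heatwave_day column or a calendar")
    flags = [
        calendar.is_heatwave(r, d)
        for r, d in zip(house_days["region"], house_days["date"])
    ]
    return pd.Series(flags, index=house_days.index, dtype=bool)


def compare_ac_vs_nonac(
    house_days: pd.DataFrame,
    daytype: str,
    calendar: HeatWaveCalendar | None = None,
) -> GroupComparison:
    """AC vs non-AC daily means on heat-wave ("HW") or other ("NHW") dates.

    One-tailed alternative: AC cooler than non-AC.
    """
    hw = _ensure_heatwave_flag(house_days, calendar)
    sub = house_days[hw if daytype == "HW" else ~hw]
    a = sub.loc[sub["ac_label"] == AC, "daily_mean"]
    b = sub.loc[sub["ac_label"] == NONAC, "daily_mean"]
    if a.empty or b.empty:
        raise ValueError(f"empty group in AC vs non-AC comparison on {daytype} days")
    return welch_one_tailed(
        a, b, alternative="a_less",
        group_a_name=f"AC/{daytype}", group_b_name=f"NONAC/{daytype}",
    )


def compare_hw_vs_nonhw_nonac(
    house_days: pd.DataFrame,
    calendar: HeatWaveCalendar | None = None,
) -> GroupComparison:
    """Heat-wave vs non-heat-wave daily means among non-AC house-days.

    One-tailed alternative: heat-wave days hotter.
    """
    nonac = house_days[house_days["ac_label"] == NONAC]
    hw = _ensure_heatwave_flag(nonac, calendar)
    a = nonac.loc[hw, "daily_mean"]
    b = nonac.loc[~hw, "daily_mean"]
    if a.empty or b.empty:
        raise ValueError("empty group in heat-wave vs non-heat-wave comparison")
    return welch_one_tailed(
        a, b, alternative="a_greater",
        group_a_name="NONAC/HW", group_b_name="NONAC/NHW",
    )


def exceedance_by_date(
    hourly: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD_C
) -> list[ExceedanceRecord]:
    """Per-date exceedance among the house-days present in ``hourly``.

    ``hourly`` is the long hourly-means table (house_id, date, hour, temp),
    already restricted to the analysis subset.  A house's duration on a
    date is its count of hour bins with mean >= threshold; the date's mean
    duration averages over all contributing houses, zeros included.
    """
    records: list[ExceedanceRecord] = []
    if hourly.empty:
        return records
    flagged = hourly.assign(above=hourly["temp"] >= threshold)
    durations = (
        flagged.groupby(["date", "house_id"], sort=True, observed=True)["above"]
        .sum()
        .astype(int)
    )
    for date, per_house in durations.groupby(level="date", sort=True):
        by_house = {h: int(v) for (_, h), v in per_house.items()}
        vals = np.fromiter(by_house.values(), dtype=int)
        records.append(
            ExceedanceRecord(
                date=date,
                n_houses_at_or_above=int((vals > 0).sum()),
                mean_duration_hours=float(vals.mean()),
                per_house_durations=by_house,
            )
        )
    return records


def hourly_heatmap(hourly: pd.DataFrame, dates: list[dt.date]) -> HeatmapMatrix:
    """Hour x date matrix of house-averaged hourly means on ``dates``."""
    values = np.full((24, len(dates)), np.nan)
    if not hourly.empty:
        cell = (
            hourly[hourly["date"].isin(set(dates))]
            .groupby(["hour", "date"], sort=True, observed=True)["temp"]
            .mean()
        )
        pos = {d: j for j, d in enumerate(dates)}
        for (hour, date), temp in cell.items():
            values[int(hour), pos[date]] = temp
    return HeatmapMatrix(dates=list(dates), values=values)


def hottest_window(matrix: HeatmapMatrix, margin: float = 0.2) -> tuple[int, int]:
    """Contiguous hour range within ``margin`` degC of the hottest hour.

    Per-hour means are averaged over the matrix dates; the returned
    half-open range [start, end) is the contiguous run of near-maximal
    hours containing the peak, ties resolved toward the earlier hour.
    """
    if matrix.values.size == 0:
        raise ValueError("empty heat map")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN hours
        profile = np.nanmean(matrix.values, axis=1)
    if np.isnan(profile).all():
        raise ValueError("heat map contains no data")
    peak = float(np.nanmax(profile))
    near = np.where(np.isnan(profile), False, profile >= peak - margin)
    if near.all():
        warnings.warn("flat hourly profile: hottest window spans the full day", stacklevel=2)
        return 0, 24
    peak_hour = int(np.nanargmax(profile))  # first maximal hour
    start = peak_hour
    while start > 0 and near[start - 1]:
        start -= 1
    end = peak_hour + 1
    while end < 24 and near[end]:
        end += 1
    return start, end
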