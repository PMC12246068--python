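"""Weekly tremor measures from window-level classifications.

Per subject-week (consecutive 7-calendar-day blocks anchored at the first
day with any data):

* tremor time - detected tremor windows as a percentage of "inactive"
  windows (windows without detected non-tremor arm movement), over daytime
  (08:00-22:00) windows of valid days;
* median, modal and 90th-percentile tremor power over the detected tremor
  windows, where the mode is the argmax of a Gaussian KDE (Silverman
  bandwidth) of the per-window log tremor powers.

A day is valid with >= 10 h of sensor data (whole day, not daytime only); a
week is valid with >= 3 valid days.  Power measures are only reported for
valid weeks whose tremor time reaches the false-positive gate (default 3.5%,
the 90th percentile of tremor time seen in non-PD controls); below the gate
the typical "tremor" window is likely a false positive and the power summary
would be meaningless.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

WINDOW_S = 4.0


@dataclass
class WeeklyTremorMeasures:
    subject_id: str
    week_index: int
    n_valid_days: int
    daytime_window_count: int
    inactive_window_count: int
    tremor_window_count: int
    tremor_time_pct: float | None
    median_power: float | None
    modal_power: float | None
    p90_power: float | None
    valid_week: bool
    gated: bool


WEEKLY_COLUMNS = list(WeeklyTremorMeasures.__dataclass_fields__)


def daytime_filter(classified: pd.DataFrame,
                   daytime_hours: tuple[int, int] = (8, 22)) -> pd.DataFrame:
    """Windows whose start time falls in [start_hour, end_hour) local time."""
    start = pd.to_datetime(classified["window_start"])
    frac_hour = (start.dt.hour + start.dt.minute / 60.0
                 + start.dt.second / 3600.0 + start.dt.microsecond / 3.6e9)
    keep = (frac_hour >= daytime_hours[0]) & (frac_hour < daytime_hours[1])
    return classified[keep.to_numpy()]


def daily_wear_hours(classified: pd.DataFrame) -> pd.Series:
    """Recorded hours per (subject, calendar day), from 4-s window counts.

    Equals the non-gap recorded time because trailing partial windows are
    shorter than 4 s per contiguous block.
    """
    day = pd.to_datetime(classified["window_start"]).dt.normalize()
    return (classified.groupby([classified["subject_id"], day])
            .size() * WINDOW_S / 3600.0)


def valid_days(classified: pd.DataFrame,
               min_hours: float = 10.0) -> set[tuple[str, pd.Timestamp]]:
    """(subject, day) pairs with at least ``min_hours`` of sensor data."""
    wear = daily_wear_hours(classified)
    return set(wear[wear >= min_hours].index)


def modal_power(values: np.ndarray, estimator: str = "kde",
                grid_size: int = 512) -> float:
    """Peak of the probability density of tremor power.

    ``kde``: argmax of a Silverman-bandwidth Gaussian KDE on a uniform grid
    spanning the observed range; ``histogram``: centre of the fullest
    Freedman-Diaconis bin.  Degenerate (near-constant) samples return their
    common value.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if v.size == 1 or np.ptp(v) < 1e-12:
        return float(v[0])
    if estimator == "kde":
        kde = gaussian_kde(v, bw_method="silverman")
        grid = np.linspace(v.min(), v.max(), grid_size)
        return float(grid[int(np.argmax(kde(grid)))])
    if estimator == "histogram":
        counts, edges = np.histogram(v, bins="fd")
        i = int(np.argmax(counts))
        return float((edges[i] + edges[i + 1]) / 2.0)
    raise ValueError(f"unknown mode estimator {estimator!r}")


def weekly_measures(classified: pd.DataFrame, gate_pct: float = 3.5,
                    daytime_hours: tuple[int, int] = (8, 22),
                    min_valid_days: int = 3, min_hours: float = 10.0,
                    mode_estimator: str = "kde") -> pd.DataFrame:
    """Aggregate window classifications into per subject-week measures.

    Input needs columns ``subject_id``, ``window_start``, ``final_state``
    and ``tremor_power``.  Every subject-week with any data yields a row;
    power fields are null unless the week is valid and the tremor time
    reaches ``gate_pct``.
    """
    df = classified.copy()
    df["window_start"] = pd.to_datetime(df["window_start"])
    df["day"] = df["window_start"].dt.normalize()
    first_day = df.groupby("subject_id")["day"].transform("min")
    df["week_index"] = ((df["day"] - first_day).dt.days // 7) + 1
    ok_days = valid_days(df, min_hours)
    df["on_valid_day"] = [
        (s, d) in ok_days for s, d in zip(df["subject_id"], df["day"])]

    rows = []
    for (subject, week), g in df.groupby(["subject_id", "week_index"],
                                         sort=True):
        n_valid = g.loc[g["on_valid_day"], "day"].nunique()
        valid_week = n_valid >= min_valid_days
        day_g = daytime_filter(g[g["on_valid_day"]], daytime_hours)
        n_daytime = len(day_g)
        inactive = day_g[day_g["final_state"] != "rejected_movement"]
        n_inactive = len(inactive)
        tremor = day_g[day_g["final_state"] == "tremor"]
        n_tremor = len(tremor)
        if n_inactive == 0:
            if valid_week:
                warnings.warn(f"{subject} week {week}: no inactive windows")
            pct = np.nan
        else:
            pct = 100.0 * n_tremor / n_inactive
        powered = (valid_week and np.isfinite(pct) and pct >= gate_pct
                   and n_tremor > 0)
        if powered:
            tp = tremor["tremor_power"].to_numpy(dtype=float)
            med = float(np.median(tp))
            mod = modal_power(tp, mode_estimator)
            p90 = float(np.percentile(tp, 90))  # linear interpolation
        else:
            med = mod = p90 = np.nan
        rows.append(WeeklyTremorMeasures(
            subject_id=subject, week_index=int(week), n_valid_days=int(n_valid),
            daytime_window_count=n_daytime, inactive_window_count=n_inactive,
            tremor_window_count=n_tremor,
            tremor_time_pct=pct, median_power=med, modal_power=mod,
            p90_power=p90, valid_week=valid_week,
            gated=bool(valid_week and not powered)))
    return pd.DataFrame([r.__dict__ for r in rows], columns=WEEKLY_COLUMNS)


def control_gate_from_cohort(control_tremor_time_pct: np.ndarray) -> float:
    """Re-derive the false-positive gate on a new cohort: the 90th percentile
    (linear interpolation) of control subject-week tremor times."""
    v = np.asarray(control_tremor_time_pct, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no control tremor-time values")
    if v.size < 10:
        warnings.warn(f"gate derived from only {v.size} control subject-weeks")
    return float(np.percentile(v, 90))
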