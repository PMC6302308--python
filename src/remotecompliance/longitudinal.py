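"""Cohort-level longitudinal compliance curves with dropout censoring.

Per-patient daily metrics are averaged across the patients still active
on each study day (patients leave both numerator and denominator from
their dropout date onward), smoothed with a trailing seven-day moving
average, and summarised as the percent change between the burn-in day
(day 14, after early-enrollment behaviour has settled) and the last
study day with any active patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig
from .engagement import METRIC_COLUMNS

COHORT_COLUMNS = ["study_day", "metric", "mean_value", "smoothed_value", "n_active"]


@dataclass(frozen=True)
class ChangeSummary:
    """Percent change of a smoothed cohort curve between two study days.

    ``percent_change`` is positive for a decline:
    ``100 * (start_value - end_value) / start_value``.
    ``study_mean`` averages the smoothed curve from ``start_day`` to
    ``end_day`` inclusive.
    """

    metric: str
    start_day: int
    end_day: int
    start_value: float
    end_value: float
    percent_change: float
    study_mean: float


def percent_change(start_value: float, end_value: float) -> float:
    """Percent decline from start to end (negative when increasing)."""
    if start_value == 0:
        raise ZeroDivisionError("percent change undefined for a zero start value")
    return 100.0 * (start_value - end_value) / start_value


def cohort_mean(daily: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Cross-patient mean of one metric per study day.

    ``daily`` must contain one row per enrolled, uncensored patient-day
    (the zero-filled contract of the daily metrics table), so the row
    count per study day is exactly the number of active patients.
    """
    if metric not in METRIC_COLUMNS:
        raise KeyError(f"unknown metric {metric!r}; valid: {sorted(METRIC_COLUMNS)}")
    col = METRIC_COLUMNS[metric]
    if col not in daily.columns:
        raise KeyError(f"metric {metric!r} (column {col!r}) not in daily table")
    grouped = daily.groupby("study_day")[col].agg(["mean", "size"]).reset_index()
    return pd.DataFrame(
        {
            "study_day": grouped["study_day"],
            "metric": metric,
            "mean_value": grouped["mean"],
            "n_active": grouped["size"].astype(int),
        }
    )


def smooth(series: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Trailing moving average of ``mean_value`` over ``window_days``.

    The window covers the current day and the previous ``window_days-1``
    days; at the start of the series it shortens to the days available,
    so smoothing never looks ahead.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    out = series.sort_values("study_day").reset_index(drop=True).copy()
    out["smoothed_value"] = (
        out["mean_value"].rolling(window_days, min_periods=1).mean()
    )
    return out


def percent_change_summary(series: pd.DataFrame, config: StudyConfig) -> ChangeSummary:
    """Summarise a smoothed cohort series per the burn-in convention.

    Start value: smoothed value at ``burn_in_day``. End value: smoothed
    value at the last study day with any active patient, capped at
    ``study_length_days``. Study mean: mean of the smoothed values over
    that span.
    """
    s = series[series["n_active"] > 0].sort_values("study_day")
    if config.burn_in_day not in set(s["study_day"]):
        raise ValueError(f"series does not cover burn-in day {config.burn_in_day}")
    end_day = int(min(s["study_day"].max(), config.study_length_days))
    span = s[(s["study_day"] >= config.burn_in_day) & (s["study_day"] <= end_day)]
    start_value = float(
        span.loc[span["study_day"] == config.burn_in_day, "smoothed_value"].iloc[0]
    )
    end_value = float(span.loc[span["study_day"] == end_day, "smoothed_value"].iloc[0])
    metric = str(series["metric"].iloc[0]) if "metric" in series.columns else ""
    return ChangeSummary(
        metric=metric,
        start_day=config.burn_in_day,
        end_day=end_day,
        start_value=start_value,
        end_value=end_value,
        percent_change=percent_change(start_value, end_value),
        study_mean=float(span["smoothed_value"].mean()),
    )


def cohort_series(daily: pd.DataFrame, config: StudyConfig,
                  metrics: list[str] | None = None) -> pd.DataFrame:
    """Smoothed cohort curves for several metrics, stacked long-form."""
    if metrics is None:
        metrics = [m for m, c in METRIC_COLUMNS.items() if c in daily.columns]
    frames = [
        smooth(cohort_mean(daily, m), config.smoothing_window_days) for m in metrics
    ]
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def change_summaries(series: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Percent-change summaries for every metric in a cohort series table."""
    rows = []
    for metric, grp in series.groupby("metric", sort=False):
        cs = percent_change_summary(grp, config)
        rows.append(
            {
                "metric": metric,
                "start_day": cs.start_day,
                "end_day": cs.end_day,
                "start_value": cs.start_value,
                "end_value": cs.end_value,
                "percent_change": cs.percent_change,
                "study_mean": cs.study_mean,
            }
        )
    return pd.DataFrame(rows)
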