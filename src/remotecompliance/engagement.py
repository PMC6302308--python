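"""Daily app-engagement counts: medication, symptoms, home assessments.

Counting conventions:

* Medication: both "take" and "skip" responses count as a report — the
  metric measures participation, not ingestion.
* Symptoms: one report event counts once regardless of how many
  symptoms it lists (one interaction with the app).
* Assessments: task events (stand_30s, sit_2min) from one patient
  within a short session window form a single assessment performance;
  a bi-daily protocol expects one performance per two-day block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig
from .events_io import active_days

DAILY_METRICS_BASE = ["patient_id", "study_day", "date"]

#: metric name -> column in the daily metrics table
METRIC_COLUMNS = {
    "medication": "medication_reports",
    "symptoms": "symptom_events",
    "assessments": "assessments",
    "streaming": "streaming_hours",
}


def _daily_counts(events: pd.DataFrame, days: pd.DataFrame, name: str) -> pd.DataFrame:
    counted = (
        events.assign(date=events["timestamp"].dt.normalize())
        .groupby(["patient_id", "date"], as_index=False)
        .size()
        .rename(columns={"size": name})
    )
    out = days.merge(counted, on=["patient_id", "date"], how="left")
    out[name] = out[name].fillna(0).astype(int)
    return out


def daily_medication_counts(events: pd.DataFrame, roster: pd.DataFrame,
                            config: StudyConfig) -> pd.DataFrame:
    """Take-plus-skip reports per enrolled patient-day, zero-filled."""
    med = events[events["event_kind"] == "medication"]
    return _daily_counts(med, active_days(roster, config), "medication_reports")


def daily_symptom_counts(events: pd.DataFrame, roster: pd.DataFrame,
                         config: StudyConfig) -> pd.DataFrame:
    """Symptom report events per enrolled patient-day (payload size ignored)."""
    sym = events[events["event_kind"] == "symptom"]
    return _daily_counts(sym, active_days(roster, config), "symptom_events")


def group_assessment_sessions(events: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Collapse assessment-task events into performances.

    A new session starts when an event falls more than
    ``assessment_session_minutes`` after the start of the current
    session; both protocol tasks done back to back therefore count as
    one performance. Returns one row per session with its start time.
    """
    ev = events[events["event_kind"] == "assessment"].sort_values(
        ["patient_id", "timestamp"], kind="mergesort"
    )
    if ev.empty:
        return pd.DataFrame(columns=["patient_id", "timestamp"])
    width = pd.Timedelta(minutes=config.assessment_session_minutes)
    rows = []
    for pid, grp in ev.groupby("patient_id"):
        session_start = None
        for ts in grp["timestamp"]:
            if session_start is None or ts - session_start > width:
                session_start = ts
                rows.append((pid, ts))
    return pd.DataFrame(rows, columns=["patient_id", "timestamp"])


def daily_assessment_counts(events: pd.DataFrame, roster: pd.DataFrame,
                            config: StudyConfig) -> pd.DataFrame:
    """Assessment performances per enrolled patient-day, zero-filled."""
    sessions = group_assessment_sessions(events, config)
    sessions = sessions.assign(event_kind="assessment")
    return _daily_counts(sessions, active_days(roster, config), "assessments")


def assessment_counts(events: pd.DataFrame, roster: pd.DataFrame, config: StudyConfig,
                      window_days: int) -> pd.DataFrame:
    """Assessment performances aggregated over windows of enrolled days.

    ``window_days=1`` gives daily counts; ``window_days=2`` (the bi-daily
    protocol cadence) sums over non-overlapping two-day blocks anchored
    at each patient's enrollment; any other value gives a trailing
    window ending at each day (used by the monitoring lookback).
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    daily = daily_assessment_counts(events, roster, config)
    if window_days == 1:
        return daily
    if window_days == 2:
        daily["block"] = (daily["study_day"] - 1) // 2 + 1
        return (
            daily.groupby(["patient_id", "block"], as_index=False)["assessments"].sum()
        )
    daily = daily.sort_values(["patient_id", "study_day"], kind="mergesort")
    daily["assessments"] = (
        daily.groupby("patient_id")["assessments"]
        .rolling(window_days, min_periods=1)
        .sum()
        .reset_index(level=0, drop=True)
        .astype(int)
    )
    return daily


def daily_metrics(
    events: pd.DataFrame,
    daily_streaming: pd.DataFrame,
    roster: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Assemble the per patient-day table of all compliance metrics.

    The assessments column is included only when assessment events
    exist (the metric is study-protocol specific). One row per
    enrolled, uncensored patient-day, zero-filled.
    """
    out = daily_medication_counts(events, roster, config)
    sym = daily_symptom_counts(events, roster, config)
    out["symptom_events"] = sym["symptom_events"].to_numpy()
    if (events["event_kind"] == "assessment").any():
        ass = daily_assessment_counts(events, roster, config)
        out["assessments"] = ass["assessments"].to_numpy()
    out = out.merge(
        daily_streaming[["patient_id", "study_day", "streaming_hours",
                         "waking_streaming_hours"]],
        on=["patient_id", "study_day"],
        how="left",
    )
    out[["streaming_hours", "waking_streaming_hours"]] = out[
        ["streaming_hours", "waking_streaming_hours"]
    ].fillna(0.0)
    return out


def metrics_present(daily: pd.DataFrame) -> list[str]:
    """Metric names available in a daily metrics table."""
    return [m for m, col in METRIC_COLUMNS.items() if col in daily.columns]
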