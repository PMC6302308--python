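"""Readers, writers and validation for the tabular event-log formats.

All stages of the pipeline exchange plain pandas DataFrames with the
column schemas below. Timestamps are naive local device time throughout:
the studies' clock-hour patterns are defined in the patient's local
time, so no timezone arithmetic is performed anywhere.

Schemas (CSV headers; JSON-Lines with the same keys is also accepted):

* roster: ``patient_id,study,enrollment_date,termination_date,age_years,
  gender,baseline_severity`` — one row per patient. ``termination_date``
  empty means the patient completed the full study.
* events: ``patient_id,timestamp,event_kind,action,payload`` —
  ``event_kind`` in {medication, symptom, assessment}; ``action``
  (take/skip) present iff medication; ``payload`` is a semicolon-joined
  symptom-label list, a numeric chorea severity, or an assessment task
  label (stand_30s / sit_2min).
* streaming hours: ``patient_id,hour_start,record_count`` — accelerometer
  records observed per clock hour; alternatively raw per-sample
  ``patient_id,timestamp`` rows, which are binned on read.
* charging: ``patient_id,start,end`` — smartwatch charging intervals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import StudyConfig

EVENT_KINDS = ("medication", "symptom", "assessment")
MEDICATION_ACTIONS = ("take", "skip")
ASSESSMENT_TASKS = ("stand_30s", "sit_2min")

ROSTER_COLUMNS = [
    "patient_id",
    "study",
    "enrollment_date",
    "termination_date",
    "age_years",
    "gender",
    "baseline_severity",
]
EVENT_COLUMNS = ["patient_id", "timestamp", "event_kind", "action", "payload"]
STREAMING_COLUMNS = ["patient_id", "hour_start", "record_count"]
CHARGING_COLUMNS = ["patient_id", "start", "end"]


class FormatError(ValueError):
    """The file does not match the declared tabular format."""


class ValidationError(ValueError):
    """The file parsed but violates a domain invariant."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson"}:
        return pd.read_json(path, lines=True, dtype={"patient_id": str})
    return pd.read_csv(path, dtype={"patient_id": str})


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _parse_timestamps(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        lines = (series.index[bad] + 2).tolist()  # +2: header + 0-based index
        raise FormatError(f"{what}: unparsable timestamp(s) at line(s) {lines[:20]}")
    return parsed


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a patient roster, validating identity and date invariants."""
    df = _read_table(path)
    _require_columns(df, ["patient_id", "study", "enrollment_date"], "roster")
    for col in ROSTER_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["enrollment_date"] = _parse_timestamps(df["enrollment_date"], "roster").dt.normalize()
    df["termination_date"] = pd.to_datetime(
        df["termination_date"], errors="coerce", format="ISO8601"
    ).dt.normalize()

    dup = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"roster: duplicate patient_id(s) {dup}")
    bad = df["termination_date"].notna() & (df["termination_date"] < df["enrollment_date"])
    if bad.any():
        raise ValidationError(
            "roster: termination_date before enrollment_date for "
            f"{df.loc[bad, 'patient_id'].tolist()}"
        )
    if (pd.to_numeric(df["age_years"], errors="coerce").dropna() < 0).any():
        raise ValidationError("roster: negative age_years")
    return df[ROSTER_COLUMNS]


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    unknown = ~df["event_kind"].isin(EVENT_KINDS)
    if unknown.any():
        raise ValidationError(
            f"events: unknown event_kind(s) {sorted(df.loc[unknown, 'event_kind'].unique())}"
        )
    med = df["event_kind"] == "medication"
    if (med & ~df["action"].isin(MEDICATION_ACTIONS)).any():
        raise ValidationError("events: medication rows require action 'take' or 'skip'")
    if (~med & df["action"].notna()).any():
        raise ValidationError("events: action only allowed on medication rows")

    sym = df[df["event_kind"] == "symptom"]
    if len(sym):
        payload = sym["payload"].astype(str)
        # label payloads (non-numeric) carry 1-8 semicolon-joined symptoms
        is_label = pd.to_numeric(sym["payload"], errors="coerce").isna()
        n_labels = payload[is_label].str.split(";").map(
            lambda xs: sum(1 for x in xs if x.strip())
        )
        if ((n_labels < 1) | (n_labels > 8)).any():
            raise ValidationError("events: symptom payload must list 1-8 symptoms")
    return df


def read_events(path: str | Path, kind_filter: str | None = None) -> pd.DataFrame:
    """Read app events, sorted by (patient_id, timestamp).

    ``kind_filter`` restricts the result to one event kind after
    validation of the whole file.
    """
    df = _read_table(path)
    _require_columns(df, ["patient_id", "timestamp", "event_kind"], "events")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["timestamp"] = _parse_timestamps(df["timestamp"], "events")
    df = _validate_events(df)
    if kind_filter is not None:
        if kind_filter not in EVENT_KINDS:
            raise ValueError(f"kind_filter must be one of {EVENT_KINDS}")
        df = df[df["event_kind"] == kind_filter]
    return (
        df[EVENT_COLUMNS]
        .sort_values(["patient_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )


def bin_raw_samples(raw: pd.DataFrame) -> pd.DataFrame:
    """Bin raw per-sample timestamps into hourly record counts.

    Hour bins are half-open [h:00, h+1:00). The summed counts conserve
    the number of raw samples.
    """
    out = (
        raw.assign(hour_start=raw["timestamp"].dt.floor("h"))
        .groupby(["patient_id", "hour_start"], as_index=False)
        .size()
        .rename(columns={"size": "record_count"})
    )
    return out[STREAMING_COLUMNS]


def validate_streaming_hours(df: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    if (df["record_count"] < 0).any():
        raise ValidationError("streaming: negative record_count")
    if (df["record_count"] > config.expected_records_per_hour).any():
        raise ValidationError(
            "streaming: record_count exceeds the physical maximum "
            f"{config.expected_records_per_hour:.0f} at {config.sampling_rate_hz} Hz"
        )
    if df.duplicated(["patient_id", "hour_start"]).any():
        raise ValidationError("streaming: duplicate (patient_id, hour_start) rows")
    return df


def read_streaming(path: str | Path, config: StudyConfig) -> pd.DataFrame:
    """Read streaming data as hourly record counts.

    Accepts either pre-binned hourly counts (``record_count`` column) or
    raw sample timestamps (``timestamp`` column), inferred from the
    header; raw samples are binned to clock hours.
    """
    df = _read_table(path)
    if "record_count" in df.columns:
        _require_columns(df, STREAMING_COLUMNS, "streaming")
        df["hour_start"] = _parse_timestamps(df["hour_start"], "streaming")
    elif "timestamp" in df.columns:
        df["timestamp"] = _parse_timestamps(df["timestamp"], "streaming")
        df = bin_raw_samples(df)
    else:
        raise FormatError("streaming: need either record_count or timestamp column")
    return validate_streaming_hours(df[STREAMING_COLUMNS], config)


def read_charging(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    _require_columns(df, CHARGING_COLUMNS, "charging")
    df["start"] = _parse_timestamps(df["start"], "charging")
    df["end"] = _parse_timestamps(df["end"], "charging")
    if (df["end"] <= df["start"]).any():
        raise ValidationError("charging: end must be after start")
    return df[CHARGING_COLUMNS]


def merge_charging_intervals(charging: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping charging intervals per patient to disjoint form."""
    if charging.empty:
        return charging.copy()
    rows = []
    for pid, grp in charging.sort_values(["patient_id", "start"]).groupby("patient_id"):
        cur_start = cur_end = None
        for start, end in zip(grp["start"], grp["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                rows.append((pid, cur_start, cur_end))
                cur_start, cur_end = start, end
        rows.append((pid, cur_start, cur_end))
    return pd.DataFrame(rows, columns=CHARGING_COLUMNS)


def active_days(roster: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Enumerate every enrolled, uncensored patient-day.

    Study day 1 is the enrollment date itself. A patient with a
    termination date is active up to the day before it (censoring
    removes the dropout date onward); otherwise through
    ``study_length_days``.

    Returns columns ``patient_id, study_day, date``.
    """
    frames = []
    for row in roster.itertuples(index=False):
        if pd.isna(row.termination_date):
            n_days = config.study_length_days
        else:
            n_days = min(
                config.study_length_days,
                int((row.termination_date - row.enrollment_date).days),
            )
        if n_days <= 0:
            continue
        dates = pd.date_range(row.enrollment_date, periods=n_days, freq="D")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": row.patient_id,
                    "study_day": np.arange(1, n_days + 1),
                    "date": dates,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "study_day", "date"])
    return pd.concat(frames, ignore_index=True)


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    out = roster.copy()
    for col in ("enrollment_date", "termination_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_streaming_hours(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out["hour_start"] = out["hour_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_charging(charging: pd.DataFrame, path: str | Path) -> None:
    out = charging.copy()
    for col in ("start", "end"):
        out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
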