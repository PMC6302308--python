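"""Daily smartwatch streaming hours with charging exclusion.

A clock hour of streaming counts toward a day's total only if the
watch transmitted at least ``valid_hour_fraction`` (default 90%) of the
records expected at the accelerometer sampling rate. Time on the
charger is excluded: charging prorates the expected-record denominator
and caps the hour's possible contribution at its non-charging fraction,
so an hour fully on the charger contributes nothing and a half-charging
hour can contribute at most 0.5 (if at least 90% of the prorated
expectation arrived).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig
from .events_io import (
    ValidationError,
    active_days,
    merge_charging_intervals,
    validate_streaming_hours,
)

DAILY_STREAMING_COLUMNS = [
    "patient_id",
    "study_day",
    "date",
    "streaming_hours",
    "waking_streaming_hours",
]


def hour_validity(
    record_count: float | np.ndarray,
    charging_fraction: float | np.ndarray,
    config: StudyConfig,
) -> float | np.ndarray:
    """Contribution of one streaming hour to the day's total, in [0, 1].

    ``effective = 1 - charging_fraction`` is the non-charging part of the
    hour; the hour contributes ``effective`` when ``record_count`` reaches
    ``valid_hour_fraction`` of the prorated expectation
    ``sampling_rate_hz * 3600 * effective``, else 0. The threshold
    comparison is inclusive: at 50 Hz with no charging, 162,000 records
    (exactly 90% of 180,000) are valid and 161,999 are not.
    """
    effective = 1.0 - np.asarray(charging_fraction, dtype=float)
    expected = config.expected_records_per_hour * effective
    ok = (effective > 0) & (
        np.asarray(record_count, dtype=float) >= config.valid_hour_fraction * expected
    )
    out = np.where(ok, effective, 0.0)
    return float(out) if out.ndim == 0 else out


def charging_hour_fractions(charging: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each clock hour covered by charging, per patient.

    Intervals are merged first so overlapping records never double
    count. Returns columns ``patient_id, hour_start, charging_fraction``
    for hours with any coverage.
    """
    merged = merge_charging_intervals(charging)
    if merged.empty:
        return pd.DataFrame(columns=["patient_id", "hour_start", "charging_fraction"])
    rows = []
    for pid, start, end in merged.itertuples(index=False):
        h = start.floor("h")
        while h < end:
            nxt = h + pd.Timedelta(hours=1)
            overlap = (min(end, nxt) - max(start, h)).total_seconds() / 3600.0
            rows.append((pid, h, overlap))
            h = nxt
    out = pd.DataFrame(rows, columns=["patient_id", "hour_start", "charging_fraction"])
    # adjacent merged intervals can split one hour across two rows
    out = out.groupby(["patient_id", "hour_start"], as_index=False)["charging_fraction"].sum()
    out["charging_fraction"] = out["charging_fraction"].clip(upper=1.0)
    return out


def daily_streaming(
    counts: pd.DataFrame,
    charging: pd.DataFrame,
    roster: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per patient-day streaming hours, total and within the waking window.

    Every enrolled, uncensored patient-day appears in the output, with
    explicit zeros for days without valid streaming. Hours outside a
    patient's enrolled days are ignored.
    """
    validate_streaming_hours(counts, config)
    unknown = set(counts["patient_id"]) - set(roster["patient_id"])
    if unknown:
        raise ValidationError(f"streaming counts for unrostered patient(s) {sorted(unknown)}")

    days = active_days(roster, config)
    if counts.empty:
        contrib = pd.DataFrame(columns=["patient_id", "date", "hour", "contribution"])
    else:
        fractions = charging_hour_fractions(charging)
        df = counts.merge(fractions, on=["patient_id", "hour_start"], how="left")
        df["charging_fraction"] = (
            pd.to_numeric(df["charging_fraction"], errors="coerce").fillna(0.0)
        )
        df["contribution"] = hour_validity(
            df["record_count"].to_numpy(), df["charging_fraction"].to_numpy(), config
        )
        df["date"] = df["hour_start"].dt.normalize()
        df["hour"] = df["hour_start"].dt.hour
        contrib = df[["patient_id", "date", "hour", "contribution"]]

    waking = contrib[
        (contrib["hour"] >= config.waking_start_hour)
        & (contrib["hour"] < config.waking_end_hour)
    ]
    total = contrib.groupby(["patient_id", "date"])["contribution"].sum()
    waking_total = waking.groupby(["patient_id", "date"])["contribution"].sum()

    out = days.merge(
        total.rename("streaming_hours"), on=["patient_id", "date"], how="left"
    ).merge(
        waking_total.rename("waking_streaming_hours"), on=["patient_id", "date"], how="left"
    )
    out[["streaming_hours", "waking_streaming_hours"]] = out[
        ["streaming_hours", "waking_streaming_hours"]
    ].fillna(0.0)
    return out[DAILY_STREAMING_COLUMNS]
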