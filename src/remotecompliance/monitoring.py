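"""Twice-weekly compliance monitoring: streaming score and assessment rule.

The monitoring rule checks two criteria at each query date:

1. A weighted streaming score over the last three calendar days. A
   *compliant day* streams at least 90% of the 09:00-21:00 waking
   window (>= 10.8 h by default). The day before the query is worth 4
   points, two days before 2, three days before 1; non-compliant days
   score 0. A total below 3 raises the streaming flag — so only
   patterns whose most recent compliant day is also recent enough
   (score in {0, 1, 2}) are flagged.
2. Fewer than 3 assessment performances over the previous 8 days
   raises the assessment flag.

A patient is recommended for contact when either flag is raised.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig

MONITORING_COLUMNS = [
    "patient_id",
    "query_date",
    "score",
    "streaming_flag",
    "assessment_count_8d",
    "assessment_flag",
    "contact_recommended",
]


def is_compliant_day(waking_streaming_hours: float, config: StudyConfig) -> bool:
    """A compliant day streams >= 90% of the waking window (inclusive)."""
    threshold = config.valid_hour_fraction * config.waking_window_hours
    return bool(waking_streaming_hours >= threshold)


def streaming_score(flags: Sequence[bool], config: StudyConfig) -> float:
    """Weighted sum of compliant-day flags for (1, 2, 3) days ago."""
    if len(flags) != 3:
        raise ValueError("flags must cover exactly (1, 2, 3) days before the query")
    return float(sum(w * bool(f) for w, f in zip(config.score_weights, flags)))


def default_schedule(start: pd.Timestamp, end: pd.Timestamp,
                     weekdays: tuple[int, ...] = (0, 3)) -> pd.DatetimeIndex:
    """Twice-weekly query dates (Mondays and Thursdays by default)."""
    days = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize())
    return days[days.weekday.isin(weekdays)]


def run_monitoring(
    daily_streaming: pd.DataFrame,
    roster: pd.DataFrame,
    config: StudyConfig,
    schedule: Iterable[pd.Timestamp],
    daily_assessments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate both monitoring criteria for every patient and query date.

    ``daily_streaming`` needs ``patient_id, date, waking_streaming_hours``;
    ``daily_assessments`` (optional, for protocols with home assessments)
    needs ``patient_id, date, assessments``. Days with no row — before
    enrollment, after dropout, or simply unobserved — count as
    non-compliant, which is the conservative reading for early-study
    queries. The assessment lookback covers the 8 calendar days strictly
    before the query date. Queries outside a patient's enrollment period
    are skipped.
    """
    schedule = pd.DatetimeIndex(sorted(pd.Timestamp(d).normalize() for d in schedule))
    compliant = {
        (row.patient_id, row.date): is_compliant_day(row.waking_streaming_hours, config)
        for row in daily_streaming.itertuples(index=False)
    }
    assessments: dict[tuple[str, pd.Timestamp], int] = {}
    if daily_assessments is not None:
        assessments = {
            (row.patient_id, row.date): int(row.assessments)
            for row in daily_assessments.itertuples(index=False)
        }

    one_day = pd.Timedelta(days=1)
    rows = []
    for patient in roster.itertuples(index=False):
        enrolled = patient.enrollment_date
        last = (
            enrolled + pd.Timedelta(days=config.study_length_days - 1)
            if pd.isna(patient.termination_date)
            else min(
                patient.termination_date - one_day,
                enrolled + pd.Timedelta(days=config.study_length_days - 1),
            )
        )
        for q in schedule:
            if q < enrolled or q > last:
                continue
            flags = [
                compliant.get((patient.patient_id, q - k * one_day), False)
                for k in (1, 2, 3)
            ]
            score = streaming_score(flags, config)
            s_flag = score < config.score_threshold
            if daily_assessments is not None:
                count8 = sum(
                    assessments.get((patient.patient_id, q - k * one_day), 0)
                    for k in range(1, config.assessment_lookback_days + 1)
                )
                a_flag = count8 < config.assessment_min_count
            else:
                count8, a_flag = 0, False
            rows.append(
                (
                    patient.patient_id,
                    q,
                    score,
                    s_flag,
                    count8,
                    a_flag,
                    s_flag or a_flag,
                )
            )
    return pd.DataFrame(rows, columns=MONITORING_COLUMNS)
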