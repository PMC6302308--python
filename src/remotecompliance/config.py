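"""Study-protocol configuration shared by every pipeline stage.

The defaults encode the protocol parameters common to six-month remote
trials of movement disorders with a streamed smartwatch accelerometer
(50 Hz), an app-based event log, and a twice-weekly compliance
monitoring rule: a streaming hour counts only when at least 90% of the
expected records arrived; a compliant day streams at least 90% of the
09:00-21:00 waking window; the monitoring score weights the last three
calendar days 4/2/1 and flags patients scoring below 3, or performing
fewer than 3 structured home assessments in the previous 8 days.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class StudyConfig:
    """Protocol parameters for one study.

    Attributes
    ----------
    sampling_rate_hz:
        Accelerometer sampling rate of the smartwatch, in Hz.
    valid_hour_fraction:
        Fraction of the expected record count (and of the waking window)
        required for a streaming hour (day) to count; in (0, 1].
    waking_start_hour, waking_end_hour:
        Clock hours bounding the waking window, half-open
        [start:00, end:00).
    study_length_days:
        Protocol study duration in days (six months by default).
    burn_in_day:
        First study day used for longitudinal summaries; early-enrollment
        behaviour before this day is excluded as unrepresentative.
    smoothing_window_days:
        Width of the trailing moving average applied to cohort curves.
    score_weights:
        Monitoring-score weights for 1, 2 and 3 days before the query
        date, in that order.
    score_threshold:
        Scores strictly below this trigger a streaming flag.
    assessment_lookback_days, assessment_min_count:
        The home-assessment criterion: at least ``assessment_min_count``
        performances over the previous ``assessment_lookback_days`` days.
    assessment_session_minutes:
        Assessment-task events from one patient within this window are
        grouped into a single performance.
    """

    sampling_rate_hz: float = 50.0
    valid_hour_fraction: float = 0.9
    waking_start_hour: int = 9
    waking_end_hour: int = 21
    study_length_days: int = 182
    burn_in_day: int = 14
    smoothing_window_days: int = 7
    score_weights: tuple[float, float, float] = (4.0, 2.0, 1.0)
    score_threshold: float = 3.0
    assessment_lookback_days: int = 8
    assessment_min_count: int = 3
    assessment_session_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not 0 < self.valid_hour_fraction <= 1:
            raise ValueError("valid_hour_fraction must be in (0, 1]")
        if not 0 <= self.waking_start_hour < self.waking_end_hour <= 24:
            raise ValueError("waking window must satisfy 0 <= start < end <= 24")
        for name in (
            "study_length_days",
            "burn_in_day",
            "smoothing_window_days",
            "assessment_lookback_days",
            "assessment_min_count",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if len(self.score_weights) != 3 or any(w < 0 for w in self.score_weights):
            raise ValueError("score_weights must be three nonnegative numbers")
        if self.assessment_session_minutes <= 0:
            raise ValueError("assessment_session_minutes must be positive")

    @property
    def waking_window_hours(self) -> float:
        """Length of the waking window, in hours (default 12)."""
        return float(self.waking_end_hour - self.waking_start_hour)

    @property
    def expected_records_per_hour(self) -> float:
        """Physical maximum record count of one streaming hour."""
        return self.sampling_rate_hz * 3600.0

    @classmethod
    def from_toml(cls, path: str | Path) -> "StudyConfig":
        """Load a configuration from a TOML key-value file.

        Unknown keys are rejected so that typos fail loudly.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "score_weights" in raw:
            raw["score_weights"] = tuple(raw["score_weights"])
        return cls(**raw)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")
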