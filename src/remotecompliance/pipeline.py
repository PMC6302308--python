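"""End-to-end assembly of every analysis table from one input bundle."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .engagement import METRIC_COLUMNS, daily_metrics, metrics_present
from .events_io import read_charging, read_events, read_roster, read_streaming
from .longitudinal import change_summaries, cohort_series
from .monitoring import default_schedule, run_monitoring
from .patterns import (
    covariate_correlation,
    hourly_event_profile,
    hourly_streaming_profile,
    pairwise_metric_correlation,
    patient_summaries,
    weekend_comparison,
)
from .streaming import daily_streaming


def compute_study(
    roster: pd.DataFrame,
    events: pd.DataFrame,
    streaming_hours: pd.DataFrame,
    charging: pd.DataFrame,
    config: StudyConfig | None = None,
    holidays: tuple = (),
) -> dict[str, pd.DataFrame]:
    """Run the full compliance analysis and return every output table.

    Tables: ``daily_streaming``, ``daily_metrics``, ``cohort_series``,
    ``change_summary``, ``monitoring_flags``, ``hourly_profiles``,
    ``patient_summaries``, ``correlations``, ``covariate_correlations``
    and ``weekend_test``. Protocols without home assessments simply
    lack the assessment columns/rows.
    """
    config = config or StudyConfig()
    ds = daily_streaming(streaming_hours, charging, roster, config)
    daily = daily_metrics(events, ds, roster, config)
    metrics = metrics_present(daily)

    series = cohort_series(daily, config, metrics)
    changes = change_summaries(series, config)

    has_assessments = "assessments" in metrics
    schedule = default_schedule(
        roster["enrollment_date"].min(),
        roster["enrollment_date"].max() + pd.Timedelta(days=config.study_length_days),
    )
    assess_daily = (
        daily[["patient_id", "date", "assessments"]] if has_assessments else None
    )
    flags = run_monitoring(ds, roster, config, schedule, assess_daily)

    profiles = []
    for m in metrics:
        if m == "streaming":
            prof = hourly_streaming_profile(streaming_hours, charging, config,
                                            normalization="count")
        else:
            kind = {"medication": "medication", "symptoms": "symptom",
                    "assessments": "assessment"}[m]
            prof = hourly_event_profile(events, kind, normalization="count")
        prof.insert(0, "metric", m)
        profiles.append(prof)
    hourly = pd.concat(profiles, ignore_index=True)

    summaries = patient_summaries(daily, roster)
    corr = pairwise_metric_correlation(summaries, metrics)
    cov = pd.concat(
        [covariate_correlation(summaries, c, metrics)
         for c in ("age_years", "baseline_severity")],
        ignore_index=True,
    )
    wt = weekend_comparison(daily, "streaming", holidays)
    weekend = pd.DataFrame(
        [{
            "metric": wt.metric,
            "mean_weekday": wt.mean_weekday,
            "mean_weekend": wt.mean_weekend,
            "t": wt.t_statistic,
            "p": wt.p_value,
        }]
    )

    corr_long = corr.stack().rename_axis(["metric_a", "metric_b"]).reset_index(name="r")
    return {
        "daily_streaming": ds,
        "daily_metrics": daily,
        "cohort_series": series,
        "change_summary": changes,
        "monitoring_flags": flags,
        "hourly_profiles": hourly,
        "patient_summaries": summaries,
        "correlations": corr_long,
        "covariate_correlations": cov,
        "weekend_test": weekend,
    }


def compute_from_dir(input_dir: str | Path,
                     config: StudyConfig | None = None) -> dict[str, pd.DataFrame]:
    """Read a bundle written in the interchange formats and analyse it."""
    input_dir = Path(input_dir)
    config = config or StudyConfig()
    roster = read_roster(input_dir / "roster.csv")
    events = read_events(input_dir / "events.csv")
    streaming = read_streaming(input_dir / "streaming_hours.csv", config)
    charging_path = input_dir / "charging.csv"
    if charging_path.exists():
        charging = read_charging(charging_path)
    else:
        charging = pd.DataFrame(columns=["patient_id", "start", "end"])
    return compute_study(roster, events, streaming, charging, config)
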