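"""Hourly/weekday profiles and per-patient correlation structure.

Answers three descriptive questions about a cohort: when during the
day do patients interact with the protocol (clock-hour profiles), does
engagement sag on weekends and holidays (two-sample t-test on
patient-days), and do compliant patients tend to be compliant across
all metrics (pairwise Spearman correlations of per-patient means,
optionally against demographic covariates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import StudyConfig
from .engagement import METRIC_COLUMNS
from .streaming import charging_hour_fractions, hour_validity

NORMALIZATIONS = ("count", "fraction", "mean-per-active-day")


def _normalize(bins: np.ndarray, normalization: str, n_patient_days: int | None) -> np.ndarray:
    if normalization == "count":
        return bins
    if normalization == "fraction":
        total = bins.sum()
        return bins / total if total > 0 else bins
    if normalization == "mean-per-active-day":
        if not n_patient_days:
            raise ValueError("mean-per-active-day needs n_patient_days > 0")
        return bins / n_patient_days
    raise ValueError(f"normalization must be one of {NORMALIZATIONS}")


def hourly_event_profile(
    events: pd.DataFrame,
    event_kind: str,
    normalization: str = "fraction",
    n_patient_days: int | None = None,
) -> pd.DataFrame:
    """24-bin clock-hour profile of one event kind.

    Count normalization conserves total mass (bins sum to the number of
    events); fraction bins sum to 1 when any events exist.
    """
    ev = events[events["event_kind"] == event_kind]
    bins = np.bincount(ev["timestamp"].dt.hour.to_numpy(), minlength=24).astype(float)
    values = _normalize(bins, normalization, n_patient_days)
    return pd.DataFrame({"hour": np.arange(24), "value": values,
                         "normalization": normalization})


def hourly_streaming_profile(
    counts: pd.DataFrame,
    charging: pd.DataFrame,
    config: StudyConfig,
    normalization: str = "fraction",
    n_patient_days: int | None = None,
) -> pd.DataFrame:
    """Clock-hour profile of valid streaming, weighted by hour validity."""
    fr = charging_hour_fractions(charging)
    df = counts.merge(fr, on=["patient_id", "hour_start"], how="left")
    df["charging_fraction"] = (
        pd.to_numeric(df["charging_fraction"], errors="coerce").fillna(0.0)
    )
    contrib = hour_validity(
        df["record_count"].to_numpy(), df["charging_fraction"].to_numpy(), config
    )
    bins = np.zeros(24)
    np.add.at(bins, df["hour_start"].dt.hour.to_numpy(), contrib)
    values = _normalize(bins, normalization, n_patient_days)
    return pd.DataFrame({"hour": np.arange(24), "value": values,
                         "normalization": normalization})


@dataclass(frozen=True)
class WeekendTest:
    """Weekday vs weekend/holiday comparison of one daily metric."""

    metric: str
    mean_weekday: float
    mean_weekend: float
    n_weekday: int
    n_weekend: int
    t_statistic: float
    p_value: float


def weekend_comparison(
    daily: pd.DataFrame,
    metric: str,
    holidays: Iterable[pd.Timestamp] = (),
) -> WeekendTest:
    """Two-sided Student's t-test of a metric on weekend/holiday vs weekday.

    The unit of analysis is the patient-day (days treated as
    independent, as a purely descriptive screen); Saturdays, Sundays
    and any supplied holiday dates form the weekend group.
    """
    col = METRIC_COLUMNS[metric]
    holidays = {pd.Timestamp(h).normalize() for h in holidays}
    dates = pd.to_datetime(daily["date"])
    is_weekend = (dates.dt.weekday >= 5) | dates.isin(holidays)
    weekend = daily.loc[is_weekend, col].to_numpy(dtype=float)
    weekday = daily.loc[~is_weekend, col].to_numpy(dtype=float)
    if len(weekend) == 0 or len(weekday) == 0:
        raise ValueError("weekend comparison needs both groups non-empty")
    t, p = stats.ttest_ind(weekday, weekend)
    return WeekendTest(
        metric=metric,
        mean_weekday=float(weekday.mean()),
        mean_weekend=float(weekend.mean()),
        n_weekday=len(weekday),
        n_weekend=len(weekend),
        t_statistic=float(t),
        p_value=float(p),
    )


def patient_summaries(daily: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean daily value of each metric over enrolled days.

    The daily table is already censored (rows exist only for enrolled,
    uncensored days), so a plain mean per patient is the right summary.
    Demographic covariates are joined from the roster.
    """
    cols = [c for c in METRIC_COLUMNS.values() if c in daily.columns]
    means = daily.groupby("patient_id", as_index=False)[cols].mean()
    return means.merge(
        roster[["patient_id", "age_years", "baseline_severity"]],
        on="patient_id",
        how="left",
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    r, _ = stats.spearmanr(x, y)
    return float(r)


def pairwise_metric_correlation(summaries: pd.DataFrame,
                                metrics: list[str] | None = None) -> pd.DataFrame:
    """Spearman rank-correlation matrix of per-patient metric means.

    Average ranks break ties. Pairs undefined (constant metric or < 3
    patients) are NaN; the diagonal is 1.
    """
    if metrics is None:
        metrics = [m for m, c in METRIC_COLUMNS.items() if c in summaries.columns]
    cols = [METRIC_COLUMNS[m] for m in metrics]
    n = len(metrics)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sub = summaries[[cols[i], cols[j]]].dropna()
            r = _spearman(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy())
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=metrics, columns=metrics)


def covariate_correlation(summaries: pd.DataFrame, covariate: str,
                          metrics: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlation of each metric's per-patient mean with a covariate.

    ``covariate`` is ``age_years`` or ``baseline_severity``. Returns one
    row per metric with the correlation and the number of patients used.
    """
    if covariate not in ("age_years", "baseline_severity"):
        raise ValueError("covariate must be 'age_years' or 'baseline_severity'")
    if metrics is None:
        metrics = [m for m, c in METRIC_COLUMNS.items() if c in summaries.columns]
    rows = []
    for m in metrics:
        sub = summaries[[METRIC_COLUMNS[m], covariate]].dropna()
        r = _spearman(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy())
        rows.append({"metric": m, "covariate": covariate, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)
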