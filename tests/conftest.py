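import numpy as np
import pandas as pd
import pytest

from remotecompliance import StudyConfig, simulate_hd_profile, simulate_pd_profile


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture
def tiny_roster():
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "study": ["PD-study", "PD-study"],
            "enrollment_date": pd.to_datetime(["2017-06-01", "2017-06-01"]),
            "termination_date": [pd.NaT, pd.Timestamp("2017-06-05")],
            "age_years": [60.0, 70.0],
            "gender": ["F", "M"],
            "baseline_severity": [20.0, 30.0],
        }
    )


def make_events(rows):
    """rows: (patient_id, iso timestamp, kind, action, payload)"""
    df = pd.DataFrame(rows, columns=["patient_id", "timestamp", "event_kind",
                                     "action", "payload"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for col in ("action", "payload"):
        df[col] = df[col].map(lambda v: np.nan if v is None else v)
    return df


@pytest.fixture(scope="session")
def small_pd_bundle():
    """A short, small PD-style cohort for fast pipeline tests."""
    return simulate_pd_profile(seed=7, n_patients=12, study_length_days=40,
                               enrollment_span_days=5)


@pytest.fixture(scope="session")
def small_hd_bundle():
    return simulate_hd_profile(seed=7, n_patients=10, study_length_days=40,
                               enrollment_span_days=5)


@pytest.fixture(scope="session")
def pd_bundle_full():
    """The full-scale default PD cohort (51 patients, 182 days)."""
    return simulate_pd_profile(seed=0)
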