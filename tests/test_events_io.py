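import numpy as np
import pandas as pd
import pytest

from remotecompliance import (
    FormatError,
    StudyConfig,
    ValidationError,
    active_days,
    merge_charging_intervals,
    read_charging,
    read_events,
    read_roster,
    read_streaming,
)
from remotecompliance.events_io import (
    bin_raw_samples,
    write_charging,
    write_events,
    write_roster,
)

from conftest import make_events


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestRoster:
    def test_minimal_row_completed(self, tmp_path):
        p = write(
            tmp_path, "roster.csv",
            "patient_id,study,enrollment_date,termination_date,age_years,gender,baseline_severity\n"
            "P1,PD-study,2017-06-01,,62,F,24\n",
        )
        r = read_roster(p)
        assert len(r) == 1
        assert pd.isna(r.loc[0, "termination_date"])

    def test_cohort_size_preserved(self, tmp_path):
        rows = "".join(f"P{i:02d},PD-study,2017-06-01,,60,F,20\n" for i in range(51))
        p = write(
            tmp_path, "roster.csv",
            "patient_id,study,enrollment_date,termination_date,age_years,gender,baseline_severity\n"
            + rows,
        )
        assert len(read_roster(p)) == 51

    def test_termination_before_enrollment_rejected(self, tmp_path):
        p = write(
            tmp_path, "roster.csv",
            "patient_id,study,enrollment_date,termination_date,age_years,gender,baseline_severity\n"
            "P1,PD-study,2017-06-10,2017-06-01,62,F,24\n",
        )
        with pytest.raises(ValidationError, match="termination"):
            read_roster(p)

    def test_duplicate_patient_rejected(self, tmp_path):
        p = write(
            tmp_path, "roster.csv",
            "patient_id,study,enrollment_date,termination_date,age_years,gender,baseline_severity\n"
            "P1,PD-study,2017-06-01,,62,F,24\nP1,PD-study,2017-06-02,,63,M,20\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_roster(p)

    def test_missing_column_named(self, tmp_path):
        p = write(tmp_path, "roster.csv", "patient_id,study\nP1,PD-study\n")
        with pytest.raises(FormatError, match="enrollment_date"):
            read_roster(p)


class TestEvents:
    def test_empty_file(self, tmp_path):
        p = write(tmp_path, "events.csv",
                  "patient_id,timestamp,event_kind,action,payload\n")
        assert len(read_events(p)) == 0

    def test_skip_counts_as_report(self, tmp_path):
        p = write(
            tmp_path, "events.csv",
            "patient_id,timestamp,event_kind,action,payload\n"
            "P1,2017-06-01T08:00:00,medication,skip,\n",
        )
        ev = read_events(p)
        assert ev.loc[0, "event_kind"] == "medication"
        assert ev.loc[0, "action"] == "skip"

    def test_symptom_payload_capped_at_eight(self, tmp_path):
        labels = ";".join(f"s{i}" for i in range(9))
        p = write(
            tmp_path, "events.csv",
            "patient_id,timestamp,event_kind,action,payload\n"
            f"P1,2017-06-01T08:00:00,symptom,,{labels}\n",
        )
        with pytest.raises(ValidationError, match="1-8"):
            read_events(p)

    def test_unknown_kind_rejected(self, tmp_path):
        p = write(
            tmp_path, "events.csv",
            "patient_id,timestamp,event_kind,action,payload\n"
            "P1,2017-06-01T08:00:00,selfie,,\n",
        )
        with pytest.raises(ValidationError, match="selfie"):
            read_events(p)

    def test_bad_timestamp_reports_line(self, tmp_path):
        p = write(
            tmp_path, "events.csv",
            "patient_id,timestamp,event_kind,action,payload\n"
            "P1,not-a-time,medication,take,\n",
        )
        with pytest.raises(FormatError, match="line"):
            read_events(p)

    def test_sorted_and_filterable(self, tmp_path):
        p = write(
            tmp_path, "events.csv",
            "patient_id,timestamp,event_kind,action,payload\n"
            "P2,2017-06-01T09:00:00,symptom,,tremor\n"
            "P1,2017-06-01T20:00:00,medication,take,\n"
            "P1,2017-06-01T08:00:00,medication,take,\n",
        )
        ev = read_events(p)
        assert ev["patient_id"].tolist() == ["P1", "P1", "P2"]
        assert ev.groupby("patient_id")["timestamp"].is_monotonic_increasing.all()
        med = read_events(p, kind_filter="medication")
        assert set(med["event_kind"]) == {"medication"}


class TestStreaming:
    def test_raw_single_hour_binned(self, tmp_path, config):
        ts = pd.date_range("2017-06-01 10:00:00", periods=100, freq="s")
        raw = pd.DataFrame({"patient_id": "P1", "timestamp": ts})
        out = bin_raw_samples(raw)
        assert len(out) == 1
        assert out.loc[0, "record_count"] == 100

    def test_raw_two_hours_counts(self, tmp_path, config):
        # brute-force oracle: assign each sample to its floor hour
        rng = np.random.default_rng(3)
        secs = np.sort(rng.integers(0, 7200, size=500))
        base = pd.Timestamp("2017-06-01 06:00:00")
        ts = base + pd.to_timedelta(secs, unit="s")
        expected = {0: int((secs < 3600).sum()), 1: int((secs >= 3600).sum())}
        raw = pd.DataFrame({"patient_id": "P1", "timestamp": ts})
        out = bin_raw_samples(raw).set_index("hour_start")["record_count"]
        assert out[base] == expected[0]
        assert out[base + pd.Timedelta(hours=1)] == expected[1]
        assert out.sum() == 500  # conservation

    def test_duplicate_hour_rows_rejected(self, tmp_path, config):
        p = write(
            tmp_path, "streaming.csv",
            "patient_id,hour_start,record_count\n"
            "P1,2017-06-01T10:00:00,1000\nP1,2017-06-01T10:00:00,2000\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_streaming(p, config)

    def test_count_above_physical_maximum_rejected(self, tmp_path, config):
        p = write(
            tmp_path, "streaming.csv",
            "patient_id,hour_start,record_count\nP1,2017-06-01T10:00:00,180001\n",
        )
        with pytest.raises(ValidationError, match="maximum"):
            read_streaming(p, config)


class TestChargingAndRoundTrip:
    def test_merge_overlapping_intervals(self):
        ch = pd.DataFrame(
            {
                "patient_id": ["P1"] * 3,
                "start": pd.to_datetime(
                    ["2017-06-01 22:00", "2017-06-01 22:30", "2017-06-02 01:00"]
                ),
                "end": pd.to_datetime(
                    ["2017-06-01 23:00", "2017-06-01 23:30", "2017-06-02 02:00"]
                ),
            }
        )
        merged = merge_charging_intervals(ch)
        assert len(merged) == 2
        total = (merged["end"] - merged["start"]).sum()
        assert total == pd.Timedelta(hours=2.5)

    def test_end_not_after_start_rejected(self, tmp_path):
        p = write(
            tmp_path, "charging.csv",
            "patient_id,start,end\nP1,2017-06-01T22:00:00,2017-06-01T22:00:00\n",
        )
        with pytest.raises(ValidationError):
            read_charging(p)

    def test_event_round_trip_exact(self, tmp_path):
        ev = make_events(
            [
                ("P1", "2017-06-01T08:15:30", "medication", "take", None),
                ("P1", "2017-06-01T12:00:00", "symptom", None, "tremor;rigidity"),
                ("P2", "2017-06-02T09:01:02", "assessment", None, "stand_30s"),
            ]
        )
        path = tmp_path / "events.csv"
        write_events(ev, path)
        back = read_events(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["patient_id", "timestamp"]).reset_index(drop=True),
            ev.sort_values(["patient_id", "timestamp"]).reset_index(drop=True),
        )

    def test_roster_round_trip(self, tmp_path, tiny_roster):
        path = tmp_path / "roster.csv"
        write_roster(tiny_roster, path)
        back = read_roster(path)
        pd.testing.assert_frame_equal(back, tiny_roster)


class TestActiveDays:
    def test_termination_day_excluded(self, tiny_roster, config):
        days = active_days(tiny_roster, config)
        p2 = days[days["patient_id"] == "P2"]
        # enrolled 06-01, terminated 06-05: active days 1..4
        assert p2["study_day"].tolist() == [1, 2, 3, 4]
        assert p2["date"].max() == pd.Timestamp("2017-06-04")

    def test_completer_gets_full_study(self, tiny_roster, config):
        days = active_days(tiny_roster, config)
        p1 = days[days["patient_id"] == "P1"]
        assert len(p1) == config.study_length_days
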