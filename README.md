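# remotecompliance

Compliance analysis for remote digital clinical trials that collect data
through a streamed smartwatch accelerometer and a smartphone app — the
setting of six-month observational studies in Parkinson's disease (PD)
and Huntington disease (HD).

The package is aimed at trial analysts and methodologists who need to
quantify **patient participation** with a remote protocol (not binary
protocol adherence) from raw event logs, and at study designers who
want to stress-test monitoring rules on realistic synthetic cohorts
before any patient is enrolled.

## What it computes

Four remote-protocol compliance metrics, per patient-day:

1. **Medication reporting** — app take/skip responses; both count as a
   report.
2. **Symptom reporting** — one report event counts once, however many
   symptoms it lists.
3. **Smartwatch data streaming** — hours per day of valid accelerometer
   streaming. A clock hour is valid when the record count reaches at
   least 90% of the expectation at the sampling rate *f* (50 Hz →
   162,000 of 180,000 records); charging time is excluded by prorating
   the expectation over the non-charging fraction of the hour.
4. **Structured home assessments** (HD-style protocols) — bi-daily
   performances of a short motor task pair, with task events grouped
   into performances by a 30-minute session window.

On top of the daily table:

* **Longitudinal curves** — cross-patient means per study day with
  dropout censoring (patients leave numerator and denominator from
  their termination date), a trailing 7-day moving average, and
  percent-change summaries from day 14 to the study end:
  `100 · (x̄₁₄ − x̄_T) / x̄₁₄`.
* **Monitoring score** — a compliant day streams ≥ 90% of the
  09:00–21:00 waking window (10.8 h); the last three calendar days are
  weighted 4/2/1 (most recent first) and a score below 3, or fewer than
  3 assessments in the previous 8 days, flags the patient for a support
  call.
* **Patterns** — clock-hour profiles, weekend/holiday t-tests, and
  Spearman rank correlations of per-patient means across metrics and
  against age or baseline disease severity.
* **Synthetic cohorts** — a seeded generator with a shared latent
  compliance propensity per patient, linear decline from a day-14
  baseline, reminder-anchored event times, a noon-centred wear block
  with nightly charging, and geometric dropout.

## Worked example

```python
from remotecompliance import (StudyConfig, simulate_pd_profile, daily_streaming,
                              daily_metrics, cohort_series, change_summaries)

bundle = simulate_pd_profile(seed=42)          # 51 patients, 182 days
config = StudyConfig()
ds = daily_streaming(bundle.streaming_hours, bundle.charging, bundle.roster, config)
daily = daily_metrics(bundle.events, ds, bundle.roster, config)
print(change_summaries(cohort_series(daily, config), config).round(2))
```

prints

```
    metric  start_day  end_day  start_value  end_value  percent_change  study_mean
medication         14      182         5.64       4.15           26.37        4.97
  symptoms         14      182         1.68       1.06           36.91        1.30
 streaming         14      182        12.52       6.80           45.65        9.93
```

Reading: on study day 14 the smoothed cohort averaged 5.64 medication
reports and 12.52 streaming hours per day; by day 182 these declined
26% and 46%, and the smoothed curves averaged 4.97 reports and 9.93 h
over the span. The `examples/` directory holds one short script per
capability (simulation, longitudinal decline, monitoring flags,
patterns and correlations).

A thin CLI wraps the same functions:

```bash
remote-compliance simulate --profile hd --seed 1 --out bundle/
remote-compliance compute --inputs bundle/ --out tables/
remote-compliance report --tables tables/ --out figures/
```

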