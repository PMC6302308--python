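"""Cohort compliance curves and six-month decline summaries.

Daily per-patient metrics are averaged over the patients still active
each study day, smoothed with a trailing 7-day moving average, and
summarised as the percent change from day 14 (after early-enrollment
behaviour settles) to the final study day.
"""

from remotecompliance import (
    StudyConfig,
    change_summaries,
    cohort_series,
    daily_metrics,
    daily_streaming,
    simulate_pd_profile,
)

bundle = simulate_pd_profile(seed=42)
config = StudyConfig()

ds = daily_streaming(bundle.streaming_hours, bundle.charging, bundle.roster, config)
daily = daily_metrics(bundle.events, ds, bundle.roster, config)
series = cohort_series(daily, config)
summary = change_summaries(series, config)

print(summary.round(2).to_string(index=False))
print()
print("percent_change > 0 is a decline from the day-14 smoothed value to the")
print("final study day; study_mean averages the smoothed curve over that span.")
n_final = series[series["metric"] == "streaming"]["n_active"].iloc[-1]
print(f"{n_final} patients were still active (uncensored) on the final day.")
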