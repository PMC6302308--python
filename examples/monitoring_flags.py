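"""Twice-weekly compliance monitoring with the weighted streaming score.

A compliant day streams at least 90% of the 09:00-21:00 waking window
(10.8 h). The last three calendar days are weighted 4/2/1 (most recent
first); a score below 3, or fewer than 3 home assessments over the
previous 8 days, recommends a support phone call.
"""

import pandas as pd

from remotecompliance import (
    StudyConfig,
    daily_metrics,
    daily_streaming,
    default_schedule,
    run_monitoring,
    simulate_hd_profile,
)

bundle = simulate_hd_profile(seed=42)
config = StudyConfig()

ds = daily_streaming(bundle.streaming_hours, bundle.charging, bundle.roster, config)
daily = daily_metrics(bundle.events, ds, bundle.roster, config)

schedule = default_schedule(
    bundle.roster["enrollment_date"].min(),
    bundle.roster["enrollment_date"].max() + pd.Timedelta(days=config.study_length_days),
)
flags = run_monitoring(ds, bundle.roster, config, schedule,
                       daily[["patient_id", "date", "assessments"]])

n = len(flags)
print(f"{n} monitoring checks across {flags['patient_id'].nunique()} patients")
print(f"streaming flag raised:  {flags['streaming_flag'].mean():6.1%} of checks")
print(f"assessment flag raised: {flags['assessment_flag'].mean():6.1%} of checks")
print(f"contact recommended:    {flags['contact_recommended'].mean():6.1%} of checks")
print()
print("score distribution (7 = all of the last three days compliant):")
print(flags["score"].value_counts().sort_index().to_string())
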