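"""Generate a synthetic remote-trial cohort and inspect its raw tables.

The simulator draws a roster with staggered enrollment and dropout, a
latent per-patient compliance propensity shared across metrics, daily
app events anchored to protocol reminder times, and hourly smartwatch
record counts from a noon-centred wear block with nightly charging.
"""

from remotecompliance import simulate_pd_profile

bundle = simulate_pd_profile(seed=42)

roster = bundle.roster
completers = roster["termination_date"].isna().sum()
print(f"cohort: {len(roster)} patients, {completers} completed the six months")
print(f"event log: {len(bundle.events)} app events "
      f"({bundle.events['event_kind'].value_counts().to_dict()})")
print(f"streaming: {len(bundle.streaming_hours)} patient-hours of accelerometer counts")
print(f"charging:  {len(bundle.charging)} charging intervals")
print()
print("first events of the first patient:")
print(bundle.events.head(5).to_string(index=False))
print()
print("A medication row is one take/skip report; record_count near 176,000")
print("is a healthy 50 Hz streaming hour (the validity rule needs >= 162,000).")
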