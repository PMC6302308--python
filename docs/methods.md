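# Methods

## Metric definitions

All four compliance metrics are computed per patient per local calendar
day. Timestamps are naive local device time everywhere: the protocols'
clock-hour rules (waking window, reminder times) are defined in the
patient's own clock, so no timezone or DST arithmetic is performed.
Study day 1 is the enrollment date itself.

**Streaming hours.** Each clock hour (half-open `[h:00, h+1:00)`)
contributes to the day's total through the hour-validity rule. With
sampling rate *f* Hz and a fraction *c* of the hour spent charging, the
non-charging fraction *e = 1 − c* prorates the expectation: the hour
contributes *e* when the observed record count is at least
`0.9 · f · 3600 · e`, else 0. At 50 Hz with no charging the boundary is
inclusive at 162,000 records. Charging intervals are merged per patient
before overlap is computed, so duplicated or overlapping charger logs
never double-count. The rule measures *streaming*, not wearing: a watch
left on a table streaming still counts, which matches how the metric is
defined in remote protocols (non-wear detection from signal magnitude
is out of scope). `waking_streaming_hours` restricts the sum to hour
bins starting inside 09:00–21:00.

**Medication and symptom reports.** Medication take and skip responses
both count (participation, not ingestion). A symptom report counts once
regardless of payload size, because it represents one interaction with
the app.

**Assessment performances.** Assessment-task events within a 30-minute
session window (configurable) form one performance, so the protocol's
task pair — stand 30 s, sit 2 min — done back to back counts once.
Bi-daily aggregation uses two-day blocks anchored at each patient's
enrollment; daily values are performances per day.

## Longitudinal aggregation

Cohort curves are computed mean-then-smooth: the cross-patient mean per
study day first (patients excluded from numerator and denominator from
their termination date onward), then a trailing moving average over 7
days (current day plus previous six, shortened at the series start).
Trailing rather than centred smoothing was chosen because it matches
real-time monitoring use and never looks ahead; with the slowly varying
curves involved the difference is a small phase shift.

Percent change is summarised from day 14 — behaviour during the first
two weeks is systematically different (device novelty, onboarding) and
is excluded — to the last study day with any active patient, capped at
the 182-day protocol length:

    percent_change = 100 · (start − end) / start

positive for a decline. The study mean averages the smoothed curve over
the same span. For bi-daily assessment endpoints of 0.95 and 0.66
performances per two days this formula gives 30.5%; that is the value
this pipeline reports for those endpoints.

## Monitoring rule

A compliant day streams at least `0.9 × 12 h = 10.8 h` of the waking
window, boundary inclusive. At each query date the last three calendar
days are weighted 4 (yesterday), 2, 1; the score is the sum over
compliant days, so the eight possible patterns map exactly onto
{0,…,7} and the flag condition `score < 3` fires iff the score is 0, 1
or 2 — equivalently, iff yesterday was non-compliant and at most one of
the two days before was compliant. Days with no record — before
enrollment, after dropout, or simply unobserved — count as
non-compliant (conservative for early-study queries). The assessment
criterion counts performances over the 8 calendar days strictly before
the query date and flags below 3. "Twice a week" defaults to Mondays
and Thursdays; the protocol does not fix the days, so the schedule is
an argument.

## Patterns and correlations

Hourly profiles bin events by local clock hour; streaming is binned by
summed hour-validity contribution. The weekend comparison is a
two-sided two-sample Student's t-test on daily values with patient-days
as independent units — a deliberate simplification (within-patient
correlation is ignored), appropriate as a descriptive screen; holidays
are supplied explicitly because holiday calendars are site-specific.
Correlations are Spearman rank correlations with average-rank ties,
computed on per-patient mean daily values over enrolled days; pairs
with a constant metric or fewer than 3 patients are reported as NaN.

## Synthetic cohort generator

The generator is the package's stand-in for raw trial data, which is
not publicly deposited. Its defaults encode the two study profiles:

| parameter | PD profile | HD profile |
|---|---|---|
| patients | 51 | 17 |
| day-14 baselines | 5.82 med, 1.61 sym, 13.32 h streaming | 1.75 med, 0.72 sym, 10.51 h, 0.95 assessments / 2 d |
| total declines | 34.2%, 43.5%, 52.7% | 2.86%, −1.39%, 20.36%, 30.5% |
| dropout hazard /day | 0.00192 (→ 36/51 completers expected) | 0.00351 (→ 9/17) |
| medication times | reminders 8, 11, 14, 17, 20 h ± jitter | morning dose in 07–12 h, evening dose 7–10 h later |
| symptom times | unscheduled, morning-leaning (≈ N(10.5 h, 3 h)) | 12:00 reminder ± 45 min |
| assessments | — | bi-daily, alternating 09:00/18:00 reminders |

Per patient *i*, a latent propensity `θᵢ ~ N(0, 0.25)` is shared across
metrics (unit loadings) plus an independent per-metric wobble
`ηᵢₘ ~ N(0, 0.21)`. The multiplicative factor `exp(θᵢ + ηᵢₘ)` is
normalised so the *realised* cohort mean is exactly 1, anchoring day-14
cohort means at the configured baselines up to count noise. The
variance split (0.25² vs 0.21²) was chosen to induce between-patient
rank correlations near 0.55 — the observed tendency of patients to be
consistently high or low across metrics — while keeping a realistic
between-patient coefficient of variation (~0.33).

Expected intensity declines linearly from the day-14 baseline to
`1 − decline` of it at day 182 (an exponential option exists for
rapid-drop scenarios). Days 1–7 apply a settling multiplier ramping to
1 (low streaming and symptom reporting, elevated assessments) so that
early-study behaviour is visibly distinct but the day-14 smoothed value
— a trailing mean over days 8–14 — is unbiased.

Event counts are Poisson at the daily intensity. Wear is realised as a
contiguous block of whole clock hours centred near 12:30 ± 1 h, giving
an hourly streaming profile that peaks around noon and collapses after
~20:00; each worn hour's record count is Binomial(expected records,
1 − 0.02), so hours pass the 90% rule unless charging overlaps. The
watch charges nightly for ~1.8 h starting ~21:48. Dropout is a constant
geometric hazard; the termination date truncates all of a patient's
output, so censoring in the analysis can be checked against the roster
exactly.

### What the generator does and does not emulate

It reproduces: magnitudes and linear trends of all four metrics,
censoring, cross-metric correlation, reminder-anchored and
preference-driven clock times, charging exclusion, and the noon-peaked
wear profile. It does not reproduce: the convex shape of real decline
curves (so simulated *study means* differ somewhat from a convex
curve's — e.g. a linear PD streaming decline averages ≈ 9.9 h where a
convex curve with the same endpoints averages less), within-patient
day-to-day autocorrelation (available as an option, off by default,
since no published value constrains it), weather/holiday seasonality,
or any accelerometer waveform content. Passing recovery tests
therefore validates the pipeline's arithmetic and the generator's
self-consistency, not the behaviour of any real cohort.

### Monte-Carlo scale of the checks

Recovery checks run the full pipeline on the 51-patient profile at
three fixed seeds and compare seed-averaged day-14 baselines (±10%)
and declines (±10 percentage points); single-seed pairwise Spearman
values are checked against a [0.35, 0.75] band. At the 17-patient HD
scale, endpoint estimates carry Monte-Carlo noise of tens of percent
(nine expected completers dominate the final-day mean), so HD runs are
exercised for structure (protocol windows, censoring, metric sets)
rather than numeric recovery. The weekend-effect type-I error check
uses 1000 replicates of a 20-patient, 8-week null cohort.

## Numerical and degenerate-input choices

* Hour bins and the waking window are half-open; validity and
  compliant-day thresholds are boundary-inclusive.
* Percent change with a zero start value raises rather than returning
  an infinity.
* A roster whose termination equals enrollment yields zero active days
  and simply contributes no rows.
* Smoothing windows shorten at the series start (`min_periods=1`);
  window 1 is the identity.
* Spearman ties use average ranks; undefined correlations are NaN, not
  zero.
* All simulator randomness flows from one `numpy` Generator seeded by
  a single integer; identical seeds give byte-identical output files.

## Known limitations

The weekend t-test ignores repeated measures per patient; monitoring
flag *rates* on synthetic HD cohorts depend strongly on how the wear
block aligns with the waking window and should not be read as estimates
of real support-call volume; and the unscheduled-call rule used in
PD-style protocols ("less compliant than expected") is qualitative and
deliberately not given a numeric trigger here.
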