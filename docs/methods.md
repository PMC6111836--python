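# Methods

## The problem

A wrist smartband that streams one heart-rate reading per minute over
Bluetooth spends most of its communication energy reporting hours in which
nothing happens. If the wearer has a regular routine, the hours in which an
elevated heart rate is plausible — exercise sessions, late nights — recur at
the same weekday/hour slots. `greenhr` learns those slots from three weeks
of data and duty-cycles the sampling schedule: 60 measurements per hour
inside predicted risky slots, 6 per hour everywhere else. Monitoring never
stops (the 10-minute cadence still catches sustained anomalies); only the
transmission count drops.

## The two-stage model

**Stage 1 — per day.** For each day, with extreme heart rates `Rmax` and
`Rmin` (bpm), the daily threshold is the weighted average

    t = (2/3)·Rmax + (1/3)·Rmin .

The weighting towards `Rmax` is deliberate: a plain average sits near the
middle of the day's range and would flag ordinary activity. Every hour
whose **mean** bpm strictly exceeds `t` becomes a *risky hourly range*
`(date, hour, mean_bpm)`. Hours with no samples contribute nothing —
absence of data is never treated as 0 bpm.

**Stage 2 — per 3-week training slot.** With `M̄` the arithmetic mean of
the three weekly maximum heart rates and ratio `Rt` (default 0.8), the
training threshold is

    Tt = M̄ · Rt .

Risky ranges whose mean exceeds `Tt` survive; the prediction for the coming
week is the **union** across the three weeks of surviving ranges, keyed by
`(weekday, hour)` with Monday = 0. Union, not intersection: a routine
present in only one training week must still be monitored. All comparisons
are strict (`>`); an hour exactly at a threshold is not risky.

The slot slides weekly. `recalculate_routines` is the mark-and-sweep
formulation: slots confirmed by the latest window are (re)marked, stale
slots are swept, so the result equals `build_prediction` on the window and a
changed routine fully ages out after three weeks.

## Energy model

Each measurement costs one Bluetooth transmission at `e_conn` watt-seconds,
bounded to [0.01, 0.05] Ws with 0.03 Ws as the working average. A weekly
plan covers 168 `(weekday, hour)` slots at 60/h (risky) or 6/h (otherwise);
low-frequency measurements fire at minutes 0, 10, …, 50 (zero phase, a
convention). Energy is `Σ freq(slot)·e_conn` against an always-on baseline
of `168·60·e_conn` per week (43.2 Ws/day, 302.4 Ws/week at 0.03 Ws). With
`k` risky hours per week the reduction is

    100·(1 − (60k + 6(168−k))/10080) ,

independent of `e_conn` and capped at 90% (`k = 0`). The stochastic
simulator redraws every transmission cost uniformly from `e_range`
(seeded, reproducible) for both the plan and the always-on control; a
zero-width range reproduces the deterministic report exactly. Batching,
retransmission, pairing, and sensor/processing energy are not modelled.

## Day-level validation

When only a few consecutive days per subject exist, the pipeline collapses
to day scale: the training day marks every hour whose hourly **maximum**
strictly exceeds that day's `t` (maxima, not means — a deliberate
difference from the weekly model, asserted by a discriminating test where
the two disagree). The next day's risk set is derived the same way, and
accuracy is the fraction of agreeing hours — risky-risky *and*
calm-calm both count — over the hours observed on **both** days. The varying
denominator (24, 23, 19, 17, …) is what real dropout produces, and is the
only reading under which per-user accuracies such as 95.65% = 22/23 are
representable. The cohort summary reports the mean and *sample* standard
deviation (n−1) of the per-user accuracies.

## Synthetic routines

The generator emulates the study conditions rather than physiology:

| parameter | default | meaning |
|---|---|---|
| `sleep_window` | (0, 8) | sleep hours, mean `sleep_bpm` = 65 bpm |
| `day_bpm_range` | (60, 100) | waking band; baseline at its midpoint, 80 bpm |
| `exercise_slots` | Thu 21–22, 120 bpm | recurring bouts; peak must exceed the band top |
| `noise_sd` | 3 bpm | i.i.d. Gaussian per minute, clipped to [40, 200] |
| `missing_rate` | 0 | uniform random deletion, < 0.2 |

A bout ramps to its peak over 10 minutes, holds, and decays back over
30 minutes ("up fast, down slowly"). Each day's random stream is keyed by
`(seed, date)`, so any day regenerates identically in isolation. Missing
data are deleted uniformly at random — real dropout (dirty glass, loose
fit) is unmodelled, so no burstiness is claimed. Minute-level means only:
no beat-to-beat variability, no heart-rate drift, no day-to-day mean
shifts. Consequently, passing recovery tests show the *pipeline* is
correct and well-conditioned under the stated noise, not that real wearers
are this separable: with a 20+ bpm margin between bout peak and waking
band, an hourly mean of 60 noisy samples moves by fractions of a bpm, so
recovery at sd 3 is essentially exact by construction.

## Numerical and design choices

* Hour buckets are half-open `[h, h+1)` local time; duplicate timestamps
  are an error (the device emits ≤ 1/min); gaps are interpolated linearly
  on the 1-minute grid within a day only, never across midnight and never
  extrapolated; the filled-point fraction is reported alongside.
* Thresholds are compared at full precision; 2-decimal rounding happens
  only in table output, avoiding rounding-order ambiguity.
* `reduction_pct` tolerates ~1e-9 relative summation round-off where a plan
  equals the baseline.
* Multi-hour published ranges decompose into unit `(weekday, hour)` slots,
  which keeps the scheduler and the energy arithmetic well defined.
* Test problem sizes: the oracle-equivalence check uses 100 random 3-week
  datasets, parameter recovery 50 noisy replicates, the Monte-Carlo cost
  check 1000 seeds — enough for the comparisons to be decisive while the
  whole suite stays fast.

## Known limitations

* Risk slots are statistical flags on one wearer's routine, not clinical
  diagnoses; heart-rate level is the only signal used.
* A training slot with no exercise anywhere drags `Tt` down to 0.8× the
  ordinary waking maximum, and ordinary waking hours can then enter the
  prediction — the method is only selective when some week contains a
  genuinely elevated maximum.
* Timestamps are assumed local; daylight-saving transitions are not given
  special treatment.
* The day-level procedure compares adjacent calendar days, which may have
  genuinely different routines (weekday vs weekend); its accuracy reflects
  that confound.
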