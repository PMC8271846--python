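# Methods

This note documents the models, rules, and numerical choices behind
`armuse`: what the pipeline computes, what the synthetic cohort generator
does and does not emulate, and where genuinely open design choices were
settled.

## Data model

The atomic unit is a 30 s epoch of 48 movement-count samples (1.6 Hz).
Counts are non-negative and dimensionless (device units).  The thigh
stream additionally carries one posture label per sample from the fixed
vocabulary LIE/SIT/STA/WAL/CYC/RUN.  A subject-week recording holds the
three sensor streams (paretic wrist, nonparetic wrist, thigh) with a
shared local-clock timebase; epoch intervals are half-open
`[start, start + 30 s)` and partial epochs at recording edges are
discarded at read time, because the 90% rule and all count sums are
defined on complete 48-sample epochs.  Clock drift between sensors is
assumed to be absent: synchronization is the pure intersection of epoch
start times, and any epoch missing from one stream is dropped from all
three.

## Preprocessing rules

All thresholds are inclusive, matching their "at least" definitions:

| rule | value |
|---|---|
| waking window | epochs starting in [07:00, 22:00) local clock |
| non-wear | zero counts for ≥ 60 min (≥ 5760 consecutive zero samples) |
| valid day | ≥ 600 min of whole-configuration wear |
| valid week | ≥ 2 valid days |
| sit/stand epoch | ≥ 90% of 48 thigh samples labelled SIT or STA |

Non-wear is detected per sensor on the concatenated 1.6 Hz sample
sequence within contiguous epoch runs, so a zero run may start mid-epoch;
an epoch is excluded when any part of it overlaps a non-wear interval
(conservative), and an epoch contributes to whole-configuration wear time
only when *no* sensor is in non-wear there.  Whether the one-hour rule
should be applied per sensor or jointly is not decidable from the outcome
definitions alone; per-sensor detection with joint exclusion is the
documented choice, and the epoch-alignment invariance of the detector is
tested explicitly.

Daily sitting/standing and walking durations are computed at sample
resolution from the thigh labels (sample count / 96 per minute), not by
epoch majority — durations should not quantize to 30 s.

## Outcomes

Per valid day: `paretic_PM`, `nonparetic_PM` sum wrist counts over all
retained epochs; `paretic_SS`, `nonparetic_SS` over the sit/stand-gated
subset; ratios are ratios of the daily sums (not means of per-epoch
ratios, which would weight epochs by their denominator).  A zero
denominator flags the ratio as undefined (NaN) rather than 0 or infinity;
undefined ratios are excluded from weekly means with the contributing
day count reported.  Weekly values are unweighted means over valid days.
Epochs failing the sit/stand gate still contribute fully to the P&M
outcomes regardless of their dominant posture — the P&M method is by
definition ungated.

## Comparison statistics

Bland–Altman: `D = mean(PM − SS)` across subjects within an outcome-week,
`SD_diff` with the n−1 denominator, limits of agreement `D ± 1.96·SD_diff`.
The percentage form divides `D` by the cohort mean of the P&M values of
that outcome-week (not per-subject percentages, which explode for small
denominators).  Absolute-scale values are always emitted alongside the
percentage.

Spearman correlations use average ranks for ties; a constant vector makes
the coefficient undefined and is flagged, not raised.  Interpretation
bands on |r|: < 0.25 very weak, < 0.50 weak, < 0.70 moderate, < 0.90
strong, otherwise very strong.  Cross-sectional correlations are computed
on weekly mean daily values per subject (one point per subject-week);
change scores are per-subject week-26 minus week-3 deltas over subjects
present at both weeks.

The GEE is a marginal Gaussian model with identity link, factors week
(categorical, reference = week 3), method (reference = sit/stand, so the
method coefficient *is* the whole-body-movement effect) and their
interaction, an exchangeable working correlation across a subject's
observations, and robust (sandwich) covariance.  Missing subject-weeks
are handled naturally by the estimating equations.  Joint Wald tests are
reported per factor.  The post-hoc family is declared in the report
header: the three between-week contrasts within each method plus the
between-method contrast within each week (nine contrasts for three
weeks), each Bonferroni-adjusted by the family size.  On balanced,
complete data with homogeneous clusters the exchangeable Gaussian GEE
reproduces OLS point estimates; the test suite asserts this identity and
additionally checks the estimator against an independent
iteratively-reweighted estimating-equation solver on unbalanced data.

## Synthetic cohort generator

The generator produces the *statistical structure* the analysis assumes,
not a biomechanical simulation.  Defaults describe a 33-subject cohort
measured for 7 days at weeks 3, 12 and 26 after stroke, inside the
07:00–22:00 window.

* **Schedules.** Daily minutes of lying/sitting/standing/walking are drawn
  per week from truncated normals and normalized to fill the 15 h window
  exactly; defaults move from 30 min walking (week 3) to 75 min (week 26)
  with sitting decreasing correspondingly — the recovery pattern the
  analysis is designed to detect.  Days are sequenced into alternating
  posture bouts with exponential lengths (mean 5 min); this produces the
  mixed epochs that exercise the 90% rule without claiming fidelity to
  any published bout model.
* **Functional bursts.** During sitting/standing samples each wrist
  receives zero-inflated gamma counts (activation probability 0.30,
  gamma shape 2, scale 10) — non-negative and right-skewed, like device
  counts.  The paretic magnitudes are scaled by a deficit multiplier
  recovering over weeks (0.35 / 0.50 / 0.60 at weeks 3 / 12 / 26).
* **Arm sway.** During walking samples each wrist receives
  truncated-Gaussian counts (paretic mean 20, nonparetic mean 25, SD 6);
  the nonparetic mean is constrained ≥ the paretic mean, reflecting the
  larger sway of the unaffected arm.  Sway is the walking-sourced
  contamination the method comparison measures; setting it to zero
  collapses the method difference to the residual leak of bursts into
  mixed bout-boundary epochs plus baseline noise.
* **Noise, non-wear, missingness.** A Poisson(0.2) per-sample baseline
  keeps worn sensors from producing spurious hour-long zero runs.
  Non-wear is emulated by zeroing a sensor's counts for a uniform 60–150
  min gap with daily probability 0.15 per sensor (an off-body device
  still records zeros; thigh labels are retained beneath the zeros).
  Subject-weeks go missing with probabilities 0.09 / 0.15 / 0.21 at
  weeks 3 / 12 / 26 — the missing-week pattern of a realistic cohort of
  this size — and days are truncated (device stops early) with
  probability 0.05.
* **Heterogeneity.** Per-subject lognormal factors on walking volume
  (σ = 0.35), burst rate (σ = 0.20) and deficit (σ = 0.10) create the
  stable between-subject variation that the cross-sectional and
  change-score correlations require.
* **Determinism.** One integer seed; every subject/week/day gets its own
  counter-based substream (`SeedSequence(seed, spawn_key=...)`), so
  enlarging the cohort or toggling one sensor's parameters never
  reshuffles unrelated draws.  Identical config + seed reproduce
  byte-identical CSV output.

Ground truth records, per emitted subject-week-day, the realized posture
minutes (exactly the emitted label stream divided by 96 samples/min), the
injected burst and sway count totals, and all non-wear intervals.  With
non-wear and missingness disabled, the pipeline recovers scheduled daily
walking minutes exactly; the acceptance suite asserts agreement within
2%.

What the generator does **not** emulate: raw-acceleration fidelity to any
specific device (counts are generated directly at 1.6 Hz), gait dynamics,
cycling/running/wheelchair transport beyond label assignment, circadian
structure within the day, or correlated bimanual activity.  Passing tests
therefore show that the pipeline implements its rules and statistics
correctly and recovers known injected structure — not that any particular
real cohort would show effects of the simulated size.

## Posture-classifier emulator

The thigh device labels postures from (1) sensor orientation relative to
gravity and (2) movement intensity.  The optional raw-mode emulator
reproduces that rule shape on 12.5 Hz tri-axial input: per 1.6 Hz output
window (7–8 raw samples), the inclination of the mean acceleration vector
against the longitudinal axis (x, distal positive) splits upright
(≤ 45°) from horizontal, and the windowed SD of the acceleration
magnitude splits quiet / moderate / vigorous at 0.08 g and 0.8 g.
Upright maps to standing / walking / running; horizontal maps to sitting
(quiet — the sitting/lying tie-break, since a single thigh sensor cannot
separate the two by inclination alone) or cycling (moving).  Thresholds
are defensible defaults and configurable; LIE appears only in directly
generated label streams.

## Problem sizes

The packaged demonstration cohort uses 12 subjects (full 7-day weeks);
parameter-recovery checks use 10–20 subjects; GEE calibration uses 30
subjects × 3 weeks × 2 methods with 100 replicates.  These sizes give
stable cohort-level statistics while keeping the full suite and the
acceptance script fast on a single CPU.  The acceptance script itself
runs the full 33-subject default configuration.

## Known limitations

* The sitting/lying tie-break makes the raw-mode emulator label lying
  patients as sitting; the count pipeline is unaffected (both are
  non-walking, non-sit/stand-gate-breaking only via the LIE label, which
  the direct generator emits correctly).
* Undefined-ratio handling (exclude-and-flag) is a documented choice;
  alternatives (treat as missing at the GEE level) would change weekly
  n's but not the count outcomes.
* The Bonferroni family size is a declared convention (9 contrasts);
  other families are defensible and would rescale adjusted p-values
  linearly.
* No bootstrap intervals for the limits of agreement and no
  mixed-effects alternatives to the GEE are provided.
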