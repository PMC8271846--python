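# armuse

Posture-gated arm-use analytics for wrist-worn accelerometry after stroke.

Wrist-worn accelerometers are a standard way to measure how much a stroke
patient actually uses the paretic arm in daily life: the sensor reports
non-negative movement counts at 1.6 Hz, stored in 30 s epochs of 48
samples, and "arm use" is the daily sum of those counts.  The catch is that
the wrist moves during *whole-body* movement too — arm sway while walking
is recorded exactly like reaching or eating.  `armuse` quantifies that
contamination by computing every arm-use outcome twice and comparing the
two methods:

* **P&M method** — counts summed over *all* retained 30 s epochs
  (all postures and movements);
* **sit/stand method** — counts summed only over epochs in which at least
  90% of the 48 samples of a thigh-worn posture sensor are labelled
  sitting or standing.

For each valid day and each method the package computes paretic arm use,
nonparetic arm use, and the ratio between arms (paretic / nonparetic of
the daily sums); weekly values are means over valid days.  The method
comparison then reports, per outcome and measurement week,

* Bland–Altman agreement: mean difference `D = mean(PM − SS)`, the SD of
  the differences, limits of agreement `D ± 1.96·SD_diff`, and `D` as a
  percentage of the cohort-mean P&M value;
* Spearman rank correlations of the method difference with daily walking
  time, cross-sectionally and as week-3 → week-26 change scores;
* a marginal Gaussian GEE with factors time (weeks 3/12/26), method, and
  time × method, exchangeable working correlation, robust standard errors,
  and Bonferroni-adjusted post-hoc contrasts.

Preprocessing follows the standard wear-validation chain: the three
streams are time-synchronized on their epoch timestamps, restricted to
waking hours (07:00–22:00), stripped of non-wear (zero counts for at
least one hour, traced at sample resolution), and a day counts only with
at least ten hours of simultaneous data from all three sensors; a week
needs at least two valid days.

Because real cohort recordings of this kind are rarely shareable, the
package ships a first-class synthetic cohort generator
(`armuse.simulate`) that emulates the three-sensor set-up — posture-bout
schedules, functional arm-use bursts with a recovering paretic deficit,
arm sway during walking, non-wear gaps, missing weeks — together with the
ground truth needed for parameter-recovery tests.

Intended users: rehabilitation researchers and methods developers working
with body-worn activity monitors who need a tested, auditable reference
implementation of posture-gated arm-use outcomes and of the statistics
used to compare them.

## Worked example

```python
from armuse import demo_config, simulate_cohort, process_cohort, \
    compare_methods, render_report

recordings, truth = simulate_cohort(demo_config(n_subjects=12, seed=0))
cohort = process_cohort(recordings)          # sync -> window -> wear -> outcomes
print(render_report(compare_methods(cohort.weekly)))
```

prints (abridged):

```
Bland-Altman mean differences (D, % of P&M mean):
     paretic week  3: D=67387.5  SDdiff=16676.9  LOA=[34700.8, 100074.2]  D%=36.4%  (n=12)
     paretic week 12: D=138981.8  SDdiff=36722.1  LOA=[67006.4, 210957.2]  D%=48.2%  (n=12)
     paretic week 26: D=163881.6  SDdiff=47518.3  LOA=[70745.9, 257017.4]  D%=47.7%  (n=9)
...
Spearman: daily walking time vs method difference:
     paretic week  3: r=1.00 (very strong, n=12)
...
GEE (Gaussian, exchangeable) Wald tests:
     paretic: week p=6.69e-27, method p=2.09e-48, week:method p=1.06e-28
```

Reading this: counting all postures (P&M) inflates daily paretic arm use
by ~36% of its mean at week 3, rising to ~48% by week 12 as the cohort
walks more; the inflation is almost perfectly rank-correlated with daily
walking time; and the GEE confirms the method effect and its growth over
time.  The sit/stand gating removes exactly the counts accrued in epochs
dominated by whole-body movement.

The same pipeline is available from the shell:

```bash
armuse simulate --config run.yaml --out sim/
armuse process  --epoch-dir sim/epochs --out proc/
armuse compare  --weekly-csv proc/weekly_outcomes.csv --out cmp/ --plots
armuse report   --compare-dir cmp/
```

All tables are flat CSVs; epoch files use one row per 30 s epoch
(`subject_id, week, sensor_role, start_time, c01..c48[, l01..l48]`).

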