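# Methods

This note documents the model and the numerical and design choices behind
`uokit`, in the spirit of the methods documentation of packages like
statsmodels or lifelines: what is computed, under which assumptions, with
which defaults, and what the synthetic-data tests do and do not establish.

## From charting events to rates

A charted urine volume has no recorded collection duration in ICU EHRs; the
duration is reconstructed as the time since the previous record **in the same
anatomical compartment**. Compartments (urinary bladder and its drainage
routes, each nephrostomy, ileal conduit) are sequential internally — two
records in one compartment describe disjoint collections — while urine
production is additive across compartments. Three rules make the
reconstruction well-defined:

* **Residual volumes.** The first record per (admission, compartment)
  accumulated before monitoring started; its volume is discarded and its
  timestamp anchors the first interval. Applied per ICU admission.
* **Simultaneous entries.** Records sharing (admission, compartment, minute)
  are double-charting of one event and are merged by summation *before*
  interval construction; entries in different compartments at the same time
  are genuinely concurrent.
* **Duration outliers.** Gaps longer than `max_duration_hr` (default 24 h)
  are charting lapses, not collections; turning them into near-zero rates
  would fabricate anuria, so the interval is dropped and counted. The
  threshold is exposed (`sweep-duration` in the CLI) because the choice is a
  judgement call; sweeping 6–48 h on simulated cohorts moves staging little,
  which matches the sensitivity analyses reported for this class of method.

Intervals are half-open `(start, end]`, so adjacent intervals in one
compartment never overlap and a record on an hour boundary belongs to the
hour it closes.

## Hourly projection and validity

For each clock-aligned hour `[HH:00, HH+1:00)` the hourly-adjusted UO is
`Σ rate_i × overlap_i`, summed over all intervals of all compartments.
Coverage is the measure of the **union** of interval time in the hour (union,
not sum: a second compartment covering the same minutes changes volume but
not coverage). An hour is valid iff coverage is strictly greater than 0.5 —
"most of the hour" read as a strict majority, so exactly 30 minutes does not
qualify; the threshold is configurable. Volumes are never renormalized by
coverage: extrapolating into uncovered minutes would manufacture data, and
the validity flag already handles partial hours. All overlap arithmetic runs
on whole minutes (charting is minute-granular in source systems), which makes
boundary cases exact; timestamps with sub-minute precision are floored on
input.

## Cleaning rules

Volumes below 0 or above 5000 ml are artifacts and are dropped record-wise;
zero is a legal volume (true anuria is charted as 0 ml, and 1–2.5 % of real
charting rows are zero-volume). Admission weights outside 25–300 kg are
artifacts; the admission and its records are dropped. Source labels indicating
urethral stents, genitourinary irrigation or urinary leaks make every volume
of that admission uninterpretable, so one such record disqualifies the whole
admission; unknown labels fail hard by default (the vocabulary is small and
should be mapped deliberately) with opt-in drop-record / exclude-admission
policies. Cleaning is idempotent, and each report partitions its input
(kept + every reason = total). Range-grouped ages/weights ("70-79", "80+")
expand to group midpoints, open tails to tail value + 5.

## KDIGO-UO staging

On the per-kg hourly series, with thresholds 0.5 / 0.5 / 0.3 ml/kg/hr over
6 / 12 / 24-h trailing windows and 12-h anuria, the stage ladder at hour *t*
is: stage 3 if the 24-h statistic < 0.3 or the trailing 12 h are exactly zero;
else stage 2 if the 12-h statistic < 0.5; else stage 1 if the 6-h statistic
< 0.5; else 0. The window statistic is the running mean (UO·mean) or the
window maximum (UO·cons — "every consecutive hour below threshold"). All
comparisons are strict, anuria is exact equality to zero (no epsilon —
records are ml-granular). A window enters the ladder only if **all** its
hours are valid and consecutive; if only the 6-h window is computable, stages
2–3 are simply unavailable that hour, and with no computable 6-h window the
hour is marked not-computable rather than stage 0. Consequences that the test
suite checks: stage_cons ≤ stage_mean pointwise, stages never decrease when
weight increases, and both interpretations equal a brute-force per-hour
window evaluation.

Thresholds and windows are configuration (`KdigoThresholds`) with guideline
defaults, since variants of the criteria circulate.

### Eligibility, peak stage and admission prevalence

Staging an admission requires a plausible known weight and ≥ 6 consecutive
valid hours; the AKI analysis additionally keeps only each patient's first
ICU admission. The peak stage is the maximum over computable hours within 72
h of the first UO record. "Diagnosis at admission" is operationalized as
stage ≥ 1 at the *earliest computable hour* — the event may have begun before
ICU arrival, which is also why the adjusted mortality model includes this
flag as a covariate.

### Serum-creatinine deltas

`scr_delta` is descriptive only: for each measurement, the baseline is the
minimum value within the preceding 7 days *including the measurement itself*
(so a fresh minimum has zero change — the natural reading of "change from the
lowest recent value"), reported as missing when no prior measurement falls in
the window.

## Cohort statistics

* **Unadjusted ORs** come from per-stage 2×2 tables against the no-AKI arm,
  with Woolf (log-OR normal) 95 % CIs and no continuity correction; zero
  cells yield explicit NaNs.
* **Adjusted marginal ORs**: one logistic model of 30-day death on stage
  (categorical) with age, weight, gender and at-admission main effects and
  stage×covariate interactions. "Marginal effect" is computed by
  g-computation — set the whole cohort to stage *s*, average the predicted
  probabilities, express the contrast to stage 0 as an odds ratio — because
  it has a clean causal reading and is directly testable against a
  generator's own g-computation. CIs are a nonparametric bootstrap over
  admissions (percentile, default 500 resamples, seeded). Only
  stage×covariate interactions are included, not all pairwise covariate
  interactions; the model formula is in `cohort._fit_logit` and the choice is
  configurable by editing it.
* **Survival**: Kaplan–Meier per stage with follow-up from ICU admission
  capped at 30 days, pairwise log-rank tests (lifelines). Datasets that only
  record hospital mortality should be censored at discharge; the generic
  path uses death timestamps.
* **Stratified summaries** choose the between-group test per declared column
  kind: ANOVA for normal, Kruskal–Wallis for skewed, chi-square for
  categorical with Fisher's exact for sparse 2×2 tables. Degenerate inputs
  (identical values in all groups) report p = 1 rather than NaN.

Logistic fits use statsmodels (Newton), survival uses lifelines, tests use
scipy; the interval/hour projection, the staging ladder, the Woolf OR and
the g-computation are implemented here.

## The synthetic generator

`simulate_cohort` emulates exactly the features of real charting the pipeline
must survive, with exact ground truth:

* **True rates** are piecewise-constant per clock hour: a log-normal baseline
  per-kg rate (median 85 ml/hr at the 81-kg reference weight, σ = 0.45,
  floored at 0.6 ml/kg/hr so that *only* modelled episodes cross the KDIGO
  cutoffs) times body weight, with an optional oliguric episode (probability
  0.5, integer onset ≤ 36 h, duration 6–36 h, depth 0.05–0.45 ml/kg/hr, 10 %
  anuric). Piecewise-constancy makes charted volumes exact integrals of the
  truth and ground-truth staging analytic.
* **Charting cadence** per source follows shifted log-normal gaps with modes
  mirroring observed practice (Foley/suprapubic/ileoconduit 60 min,
  voiding/condom 120, straight catheter 360, nephrostomy 120), clipped to
  10 min–18 h; the `hourly` mode charts exactly on clock hours for recovery
  tests. Nephrostomy patients chart two single-kidney compartments at half
  the rate each.
* **Realism quirks**: a residual first volume per compartment; ~1.5 % extra
  zero-volume rows double-charted at existing timestamps (keeping charted
  totals exact integrals of truth); mortality drawn from a logistic model in
  the true peak stage (baseline 7.2 %, ORs 1.75 / 3.3 / 7.5 — shaped like a
  large mixed-ICU cohort).
* **Artifacts** are injected only on request, with a manifest: out-of-range
  volumes and weights, exclusion-source labels, and simultaneous duplicates
  that *split* an existing volume so merging restores totals exactly.

Ground-truth stages are produced by a direct per-hour window scan — a
separate code path from the rolling-window implementation under test.
`simulate_outcomes` is a cohort-level fast path (stages and deaths only, same
mortality model) for large-n odds-ratio recovery.

What passing on synthetic data shows: the pipeline inverts the charting
process exactly wherever charting is complete, and degrades only by losing
valid hours where it is not. What it does not show: robustness to features
the generator omits — within-hour rate changes, charting-practice drift over
years, correlated missingness around clinical events, weight measured with
error. Claims about real cohorts require the real databases.

## Problem sizes and tolerances

Test and acceptance runs use cohorts of 60–300 admissions for full-pipeline
properties (a 96-h stay at hourly cadence is ~100 records per admission) and
20,000 simulated patients for cohort-level OR recovery; these sizes give
Monte-Carlo error well inside the asserted bands while keeping runs quick.
Hourly-projection equivalence is asserted to 1/120 ml and 1/60 coverage
against a per-minute oracle (the discretization's own resolution);
volume-conservation identities to 1e-6 ml; OR recovery within two
Monte-Carlo standard errors on the log scale. Bootstrap and simulation seeds
are fixed in tests and flow from `--seed` in the acceptance script.

## Known limitations

* Rates are assumed constant within each collection interval; the method
  deliberately refuses to impute uncovered time instead of modelling it.
* The at-admission flag cannot distinguish community-acquired AKI from early
  ICU-acquired AKI; prior-to-ICU urine data simply do not exist.
* The AUMC-style reader expands grouped ages/weights to midpoints, which
  slightly attenuates per-kg extremes.
* Adjusted-OR bootstrap refits can fail in small resamples (separation);
  failed resamples are dropped and counted rather than silently replaced.
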