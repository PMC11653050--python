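# Methods

## Data model and alignment

All timestamps are epoch seconds (UTC, no DST handling); the target
datasets are date-shifted for de-identification, so absolute dates carry no
meaning and input local times are taken at face value. The analysis grid is
the 5-minute CGM cadence. A channel value labelled with grid time *t*
aggregates raw samples in the half-open window [*t* − 300 s, *t*): the CGM
convention that a reading summarizes the preceding interval. The default
aggregator is the window mean; a `nearest` mode (closest sample within
150 s) exists for sensitivity checks, since the sources do not state
whether 5-minute extraction averaged or subsampled. Triaxial acceleration
is collapsed to its Euclidean norm √(x² + y² + z²) before aggregation; the
event-based IBI channel is aggregated by averaging the interval durations
of events falling in the window.

Rolling summaries are the mean and sample SD (denominator *n* − 1) over a
trailing window of three grid points — the current and two preceding
5-minute values, 10 minutes in total. A centered variant is available for
sensitivity analysis. Missingness is strict: any missing contributor makes
the summary missing, so no partial windows enter downstream sample sizes.

## Lag correlation profiles

For lag ℓ ∈ {−120, −105, …, +120} minutes, the glucose summary at *t* is
paired with the channel summary at *t* + ℓ *within* participant (a shift
never crosses participants), incomplete pairs are dropped, and the pairs
are pooled across the cohort into a single table per lag. Negative lag
means the physiological signal was measured before the glucose reading;
this sign convention is written into every output. Spearman's ρ uses
mid-ranks for ties and a two-sided *p* from the *t* approximation
t = ρ·√((n−2)/(1−ρ²)) on n − 2 df (|ρ| = 1 reports p = 0); entries with
n < 3 or degenerate ranks are flagged undefined rather than reported as 0.
The profile's peak is the lag of maximal |ρ|, earliest lag on ties, and
entries with *p* < .05 carry a significance flag matching the usual
asterisk convention of profile plots.

**Calibration caveat.** The pooled pairs are not exchangeable: glucose
summaries are smooth in time and the 3-point rolling windows of adjacent
grid points overlap, so both members of a pair are serially dependent. The
nominal *t*-approximation *p* therefore understates the variance of ρ
under the null — in simulations with all couplings disabled the *P* < .05
flag fires for roughly 17–22% of lag entries rather than 5%. This is a
property of the pooled-summary design itself, which this package
reproduces deliberately; the flags should be read as descriptive, not as
calibrated tests. (The ρ estimates themselves are unbiased under the null;
only their significance labels are optimistic. `spearman()` is exactly
calibrated when rows are independent, which the unit tests verify.)

## Postprandial excursions and slopes

Extremum identification is not specified by the sources and is
operationalized as follows: anchored at a food-log entry, the *peak* is
the maximum grid glucose in (meal, meal + horizon] with a default horizon
of 180 min; the *pre-rise trough* is the minimum in [meal, peak]; the
*post-peak nadir* is the minimum in [peak, end of span]. The next meal
truncates the span so excursions never overlap, and the earliest grid
index wins all ties. A flat span yields no excursion; a configurable
minimum amplitude (default 0) can filter noise excursions in stress tests.
Slopes are difference quotients in mg/dL per minute: rise =
(peak − trough)/(Δt), fall = (nadir − peak)/(Δt); rise ≥ 0 and fall ≤ 0 by
construction.

Window features take each channel's mean and sample SD over five half-open
windows: meal→peak (base), peak→nadir (`_af`), and the pre-meal windows
[meal−30, meal), [meal−60, meal−30), [meal−90, meal−60) (`_30`/`_60`/`_90`),
which partition the 90 pre-meal minutes. The prose description of these
windows in the source material is ambiguous; the pre-meal reading follows
the study-design figure and is recorded in output metadata. `_af` features
are computed but excluded from rise-slope models (limited data after the
peak). Nutrient totals sum field-wise over the meals between the anchor
and the peak — with next-meal truncation this is normally the anchor meal
alone; an absent nutrient field in any contributing meal clears the
`complete` flag rather than counting as zero, because a zero would silently
bias the sums.

## Regression and combination-pattern ANOVA

Ordinary least squares with intercept and complete-case deletion;
two-sided *t*-based *p* values; a rank-deficient design is a fatal error
that names the collinear column set. Backward elimination repeatedly
removes the non-forced predictor with the largest *p* while it is ≥ .20,
refitting at each step; ties remove the later column first; the ordered
removal trace is recorded so the path can be audited by replay. Sex can be
forced into the model as an adjustment covariate and is then never
removed. Candidate sets follow the slope-model structure: mean models use
the window channel means plus the six nutrient totals; SD models use the
window channel SDs only; rise-slope models exclude `_af` features.

Median splits are computed on the pooled table (a per-participant variant
exists as an option); a value exactly at the median codes 0, so the
reference all-zeros group absorbs boundary rows and stays nonempty on
small tables. Rows missing any encoded variable are excluded and counted.
Pattern groups smaller than `min_group_n` (default 5 — one
operationalization of "extremely low" group sizes, flagged in every
report) are dropped; a one-way ANOVA runs across the survivors, and each
group is contrasted against the all-zeros control with a pooled-variance
two-sample *t* test, unadjusted for multiplicity by default (a Bonferroni
option exists). With two groups F = t² exactly. Repeated excursions from
one participant are pooled as independent rows — a simplification the
design shares with the analysis it reproduces; no mixed-effects structure
is modeled.

## Synthetic cohort generator

The generator targets the statistical structure the analysis assumes, not
metabolic realism (no glucose–insulin ODE). Defaults describe the study
conditions: 16 participants, 8–10 days each, 3 meals/day with ~40 min
timing jitter.

* **Glucose.** Baseline 90 mg/dL plus, per meal, a double-exponential
  kernel A·(e^(−t/τ_fall) − e^(−t/τ_rise)) normalized to peak 1, with
  τ_rise = 15 min, τ_fall = 60 min (analytic peak ≈ 28 min after the meal,
  inside the plausible 30–60 min postprandial window once discretized) and
  amplitude A = carb_gain·carb·max(0, 1 − fiber_damping·fiber),
  carb_gain = 1 mg/dL per g, fiber_damping = 0.02 per g (a 50 g-carb meal
  peaks at ~+50 mg/dL; 10 g fiber damps it 20%). On top: an AR(1)
  physiological fluctuation (SD 5 mg/dL, φ = 0.55 per 5-min step, ~8-min
  memory — short-scale glycemic variability independent of meals) and
  white CGM sensor noise (SD 3 mg/dL), clipped to the 40–400 mg/dL sensor
  range.
* **Nutrients.** Per-meal draws with carbohydrate–calorie correlation 0.78
  and carbohydrate–protein correlation 0.49 (the correlations reported for
  the target cohort); sugar is a uniform 20–70% fraction of carbohydrate,
  so sugar ≤ carbohydrate always holds.
* **Channel couplings.** Couplings act on the 5-minute level and are then
  upsampled with native-rate noise, because the analysis only sees
  summaries. A `mean` coupling sets the channel level to a standardized
  linear function of the lag-shifted glucose (strength s, noise weight
  √(1−s²)); an `sd` coupling modulates the channel's noise scale
  multiplicatively, amp·e^(s·z), so the rolling SD tracks shifted glucose
  with the sign of s. Defaults: EDA SD at −15 min, s = −0.5; ACC SD −15,
  −0.3; HR SD −15, −0.25; TEMP mean 0, +0.3 — the qualitative pattern the
  analysis is designed to detect. Negative lag means the channel leads
  glucose.
* **Ground truth.** Each cohort carries a manifest with every parameter,
  per-meal kernel amplitudes, and "true" rise/fall slopes obtained by
  running the same detection rules on the noiseless kernel trace. The
  generator-implied nutrient effect used in recovery checks is the OLS
  coefficient of these true slopes on the nutrient totals.
* **Seeding.** Per-participant generators derive from (seed, index) via
  numpy `SeedSequence`, so cohorts are bit-reproducible and stable under
  participant-count changes; demographics and raw-rate noise use separate
  derived streams so grid-level data are unaffected by them.

What the generator does *not* emulate: motion artifacts, sensor dropout,
EDA tonic/phasic structure, BVP waveform morphology, circadian baselines,
or behavioral correlation between meals and activity. Passing tests
therefore demonstrate that the pipeline recovers known statistical
structure under clean conditions, not that it is robust to real-device
artifacts.

## Problem sizes and numerical choices

Statistical calibration checks run on grid-level cohorts (the raw-file
layer adds nothing to summary-level statistics): lag-recovery and null
calibration use 50 replicates of one participant × 7 days (~2,016 grid
points); nutrient-effect recovery uses full default cohorts (16 × 8–10
days, ~430 excursions); elimination power uses 100 replicates at n = 200
with one standardized-0.5 predictor among 9 noise predictors. End-to-end
raw-file runs use 2 participants × 8 shortened (2.5 h) days, which keeps
the native-rate files (ACC 32 Hz, BVP 64 Hz) small while still yielding
~48 meals — enough complete rows for the 30-candidate mean-feature
regression. Oracle comparisons use 1e-10–1e-12 tolerances; CSV output uses
12 significant digits, which round-trips reals to better than 1e-9
relative error and makes repeated runs byte-identical.

**Known recovery bias.** The detected carbohydrate effect on the rise
slope is mildly attenuated (≈5–15%) relative to the generator-implied
effect: for small-amplitude excursions, noise determines the argmax, which
lengthens the average trough→peak interval and flattens the slope–carb
relation. This is inherent to extremum-based slope extraction under noise
and would affect the original analysis equally; the acceptance output
reports the gap in SE units rather than hiding it.
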