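# Methods

## The score

`spiraltis` computes a Temporal Irregularity Score (TIS) for spiral
drawings captured on a touch screen as ordered `(x px, y px, t ms)`
touch events. For one trial:

1. The event stream is down-sampled by keeping every second sample
   (original indices 0, 2, 4, …). The study device sampled on
   position-change events at a higher effective rate than the reference
   device the score was developed on; halving the rate makes the two
   comparable. The phase is fixed so the trial-start sample is always
   retained, which keeps the completion-time endpoints stable.
2. Drawing speed is the Euclidean pixel displacement between
   consecutive retained samples divided by the elapsed time in seconds
   (`DS_i = sqrt(Δx² + Δy²) / Δt`), giving a series of length n − 1.
3. Approximate entropy of the speed series,
   `ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r)`, where `Φ^m` is the mean over
   window starts of `log C_i^m(r)` and `C_i^m(r)` is the fraction of
   length-m windows within tolerance `r` of window i.
4. `TIS = ApEn / completion time (s)`, and the analysis value per test
   occasion is the mean TIS over its (up to) three trials.

### Conventions

* **Distance and self-matches.** Chebyshev (max-coordinate) distance
  between embedding windows, with self-matches included — the classical
  ApEn convention, which also guarantees `C_i^m(r) > 0` so the
  logarithm is always defined. Both are configurable
  (`ApEnParams.distance`, `ApEnParams.self_match`).
* **Logarithm.** Natural log; results are in nats. The base only
  rescales all comparisons uniformly.
* **Tolerance.** `r = r_fraction × SD` of the individual trial's speed
  series (default `r_fraction = 0.2`, window length `m = 2`). A
  cohort-global SD scope (`r_scope="cohort"`) is available but off by
  default; per-trial scaling makes the statistic invariant to affine
  rescaling of a trial's speeds.
* **Degenerate inputs.** A zero-variance speed series gets `ApEn = 0`
  (a constant signal is maximally regular); series shorter than
  `m + 2` raise a degenerate-input error. Small negative values of the
  statistic — possible at short series lengths because the two Φ terms
  average over different window counts — are reported as-is, except
  that round-off within 1e−12 of zero is clamped to exactly 0. Clamping
  genuine negatives would break agreement with the statistic's defining
  formula (which the tests verify against an exhaustive reference
  implementation).
* **Completion time** is measured between the first and last sample of
  the series actually scored (after down-sampling). The difference from
  the raw endpoints is at most one inter-event interval, and a single
  data path avoids ambiguity. The identity
  `TIS × completion time = ApEn` therefore holds exactly.
* **Parameter grid search.** `parameter_grid_search` re-scores a cohort
  for each `(m, r)` on a grid (default {2, 4} × {0.1, 0.2}) and reports
  four criteria: test-retest ICC, peak patient effect size, mean
  absolute rating correlation, and the advanced-vs-healthy contrast
  magnitude |coef/SE|. No single combination rule is canonical, so the
  default ranking is an equal-weight sum of standardized criteria, with
  the weights exposed.

## The synthetic cohort

Real patient recordings for this measurement design are not publicly
available, so the package ships a simulator that reproduces the design
exactly and provides a controllable generative model for testing every
downstream stage.

**Design (fixed).** 22 healthy controls, 19 patients split 7/8/4 into
early/intermediate/advanced. Patients are tested at −20 (baseline), 0
(dose), 15, 30, 45, 60, 80, 100, 120, 150, 180, 210, 240, 300 and 360
minutes from a levodopa dose; healthy controls at 0, 20, 40, 60, 80,
110, 140 and 170 minutes from their first test. Three ~10 s trials per
occasion on a 480×800 px screen; event-based sampling with jittered
inter-event intervals (default mean 20 ms, jitter SD 4 ms). Patients
carry mean ratings on six UPDRS-III items and a 0–4 dyskinesia scale,
averaged over three simulated raters; healthy controls carry none.
Ages are drawn normal (patients 71.4 ± 6.3, healthy 64.2 ± 7.4 years)
and gender ratios match the study demographics (14/19 and 16/22 male).
An optional dropout flag truncates patient schedules deterministically
to reproduce the published attrition counts (19, 19, 19, 19, 18, 18,
18, 18, 18, 17, 15, 13, 9 patients at the post-dose timepoints, one at
360 min).

**Generative model (minimal, two knobs).** Each subject has a latent
severity (group means: healthy 0.3, early 1, intermediate 2, advanced
3, between-subject SD 0.25). A dose subtracts a gamma-shaped unimodal
effect pulse from patient severity: onset delay 10 min, peak 1.2 units
at 70 min, wearing off towards zero by 300–360 min. Severity couples to
the drawing in two ways:

* `irregularity_gain` (default 0.01 per severity unit) scales the
  amplitude of band-limited multiplicative noise on the instantaneous
  drawing speed. The pen traverses an Archimedean spiral center-out at
  `v(t) = v0 (1 + drift + amp · ε_t)` with a low-frequency sinusoidal
  drift (amplitude 0.15) and lightly smoothed white noise `ε`. ApEn of
  the resulting speed series rises steeply with `amp` up to roughly 4%
  of base speed and then saturates, so the default gain places the four
  group severities on the steep, monotone part of that response.
* `completion_time_gain` (default 0.05 per severity unit) slows the
  whole trial down, which *lowers* TIS through the 1/time
  normalization.

The two couplings expose both directions of the severity→score
relationship. Under the defaults mean occasion TIS increases with group
severity; `weak_correlation_config()` is a second, frozen regime
(`irregularity_gain = 0.0005`, severity-independent occasion-level
amplitude noise SD 0.005, `completion_time_gain = 0.15`) in which the
entropy numerator is essentially uninformative about severity and the
score *decreases* with severity through drawing slow-down — while
correlations between the score and the clinical ratings stay weak,
because the ratings track slow severity and the score is dominated by
occasion-to-occasion high-frequency variability invisible to a rater.

**Ratings.** The six UPDRS items are clipped linear maps of
instantaneous severity (slope ≈ 1.1 per severity unit, floor 0.2) plus
independent per-rater Gaussian noise (SD 0.3), clipped to [0, 4] and
averaged over three raters. Dyskinesia instead follows the medication
effect lagged by 10 min, scaled by baseline severity — it peaks at
On-with-dyskinesia, when the effect is maximal, not when severity is.

**What the simulator does not model:** biomechanically realistic
tremor spectra, pharmacokinetics beyond a single unimodal pulse,
spatial drawing errors (the pen never leaves the spiral), integer pixel
quantization, or rater disagreement structure. Passing tests therefore
demonstrate that the pipeline recovers the relationships the generator
encodes at the study's sample sizes — not that the score has these
properties in patients.

## Statistical battery

On a scored table (one row per subject × occasion):

* **Group contrasts.** `occasion_tis ~ group + age` with a subject
  random intercept, fitted by REML (statsmodels `MixedLM`), healthy as
  reference, giving early/intermediate/advanced contrasts; the pooled
  all-patients contrast comes from a second fit with a binary patient
  indicator rather than a post-hoc sum of stage contrasts. A constant
  age column drops the covariate; a singular fit falls back to OLS and
  is flagged `converged=False`.
* **Test-retest reliability.** Single-measure ICC over the grand
  occasion × trial matrix (every occasion is a target, the three
  repeated trials are the "raters"), default two-way mixed-effects
  consistency form ICC(3,1) via pingouin, since the three repeats are a
  fixed set; one-way random and absolute-agreement variants are
  selectable. Occasions missing a trial are excluded by default.
* **Gender.** Fisher's exact test (two-sided) on the
  patients-vs-healthy × male/female table.
* **Treatment response.** For each post-baseline timepoint, a one-way
  ANOVA between baseline and timepoint scores of the subjects observed
  at both, summarized as eta-squared (`SS_between / SS_total`);
  |Cohen's d| is available as an alternative. The patient baseline is
  the −20 min occasion (the pre-dose measurement; 0 min is a regular
  timepoint), the healthy baseline their first test at 0 min.
  Timepoints with fewer than 2 paired subjects are dropped — at the
  default sizes with dropout enabled this removes the 360 min point,
  as in the study.
* **Rating correlations.** Pearson r between the occasion score and
  each mean rating scale over all patient occasions with both present
  (≥ 3 pairs per scale). Raw p-values are reported without
  multiple-testing correction, matching the study's reporting; a
  correction switch is left to users.

## Problem sizes and determinism

All simulations are driven by a single `numpy` Generator seeded from
the config, so a fixed config reproduces cohorts byte-identically. The
test suite calibrates the estimators at deliberately modest sizes: 200
occasions for reliability recovery, 50 simulated cohorts for the
mixed-model error rates (score-level generation, which bypasses trial
rendering and isolates the estimator), 20 full rendered cohorts for the
medication-response curve, and 3 for the weak-correlation regime. The
default rendered cohort (41 subjects, 416 occasions, 1248 trials of
~250 speed samples after down-sampling) scores in roughly ten seconds
on one core.

## Known limitations

* ApEn at these series lengths (~250 samples) is strongly biased
  relative to its asymptotic value; comparisons are only meaningful at
  matched lengths, which the pipeline preserves by fixing trial
  duration and sampling rate within a cohort.
* The ApEn-vs-amplitude response saturates, so the simulator cannot
  represent arbitrarily graded irregularity; group placement on the
  response curve is a modelling choice.
* The completion-time normalization makes the score's direction with
  severity depend on the balance of the two couplings; both regimes are
  available and tested, and neither is claimed to be the truth about
  patients.
* The grand-matrix ICC treats occasions from the same subject as
  independent targets; a subject-stratified pooling is not implemented.
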