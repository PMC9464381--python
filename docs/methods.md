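# Methods

## Problem and model

`riskscreen` studies how much screening effort can be saved by allocating a
limited number of examinations using *time-dependent* individual risk
predictions instead of allocating them uninformedly, while holding the
population-level detection benefit fixed.

The model world is deliberately stylised:

* A population of N initially disease-free individuals is followed over
  `n_intervals` annual intervals (default 5).  An examination can only
  happen at the end of an interval, at t = i years.
* Individual k carries conditional annual risks p_{k,i}: the probability of
  disease onset in interval i given no earlier event.  Prediction accuracy
  is treated as perfect, so each p_{k,i} is carried through the accounting
  as *expected occurrence mass* located at the interval midpoint
  t_occ = i − 0.5; no binary events are sampled in simulation mode.  All
  detection quantities are therefore exact expectations, which removes one
  whole layer of Monte-Carlo noise.
* An occurrence detected with delay d is still curable with probability
  dp^d.  The base dp encodes progression speed: 0.6 slow, 0.3 intermediate,
  0.1 fast.  Under full screening every occurrence is caught at the minimum
  delay of half a year, which defines the denominator n_max of the target
  detection rate tdr = n_actual / n_max.

## Population generator

Two-stage sampling, driven by three scenario parameters:

1. **Mean trajectory.**  The five population mean annual risks are drawn
   from standard normals and affinely standardised to an exact sample mean
   of `mean_5y_risk / n_intervals` (default 2%) and an exact sample SD of
   `sdmr = cvmr × mean annual risk`.  The trajectory is redrawn (up to 100
   times) if any mean falls below 1e-4; for extreme `cvmr` this fails and is
   reported as an invalid parameter.  Exact-moment standardisation makes the
   `cvmr → sdmr` mapping (0.5 → 1%, 0.25 → 0.5%, 0.05 → 0.1%) hold for every
   seed, not just in expectation.  A fresh trajectory is drawn for every
   repetition of a scenario.
2. **Individual matrix.**  Around the trajectory, each patient's five annual
   risks are jointly normal with equicorrelation r (one-factor construction,
   so the pre-truncation pairwise correlation is exactly r), per-year spread
   `sigma_i = sigma_scale / |log10(m_i)|`, truncated at zero and then each
   column multiplicatively rescaled back to its trajectory mean.  Rescaling
   (rather than resampling) keeps the population occurrence mass — and hence
   the tdr denominator — exactly conserved.

The per-year spread rule deserves emphasis because it is the one genuinely
free modelling choice: only the qualitative statement "spread is inversely
related to the log of the year's mean risk" is available, with no functional
form or scale.  We use `sigma_scale / |log10 m_i|` with `sigma_scale = 0.01`
(risk units): at a 2% mean annual risk this gives an individual SD of
≈ 0.59 percentage points per year.  The choice is exposed in every config
surface and recorded in each run manifest, because the efficiency of the
*time-independent* cumulative strategy — and the savings of all strategies
in low-`cvmr` scenarios — scale directly with this between-patient
heterogeneity.  Sensitivity runs at other values of `sigma_scale` can be
produced with the same grid runner (`--sigma-scale`).

## Detection accounting

For a schedule S (an N × n 0/1 matrix), the occurrence mass of interval i is
examined by the patient's exams at years j ≥ i in order; with examination
sensitivity s the q-th such exam (q = 0, 1, …) detects it with probability
s(1−s)^q, weighted by the curability dp^(j−i+0.5).  Setting s = 1 collapses
the cascade to "the first subsequent exam detects".  n_max applies the same
cascade to the full schedule, so tdr remains a ratio of like quantities and
full screening always has tdr = 1 regardless of s.  A "flat" mode (only the
first subsequent exam can detect, with probability s) is available for
comparison; the cascade is the default.  The vectorised implementation is
checked against a naive patient × occurrence × exam triple loop to 1e-12 in
the test suite.

## Strategies and calibration

* **CA** screens a patient every year iff their summed 5-year risk reaches
  the threshold — risk-based but time-independent.
* **CAIR** accumulates annual risks until the threshold is reached,
  schedules an exam at the end of that year, resets, and continues.
* **ISA** screens after exactly the years whose own annual risk reaches the
  threshold.
* **RA** draws uniformly random patient-year slots one at a time and stops
  at the first draw whose schedule reaches the target tdr.

Threshold comparisons are inclusive, so threshold 0 is the full schedule for
every rule.  For each rule the threshold meeting a target tdr is found by
bisection on [0, max relevant risk sum] down to a bracket width of 1e-8 risk
units, exploiting that achieved tdr is non-increasing in the threshold
(exact for CA and ISA by schedule nesting; for CAIR micro-violations of
order ≤ 1e-2 in tdr exist because resets break nesting, but the bisection
update rule maintains the bracket invariant tdr_lo ≥ target > tdr_hi by
construction, so no monotone-envelope fallback is needed).  Because discrete
schedules cannot hit the target exactly, the exam count "at" the target is
defined by linear interpolation between the bracketing plateaus; both raw
brackets are reported.  Degenerate brackets (equal tdr on both sides)
resolve to the fewer-exams side.

**RA accounting.**  The stop index is located by bisection over the prefix
length of the draw sequence, which is equivalent to one-at-a-time drawing
because adding an exam never decreases expected detections.  Two counts are
reported: `exams` (distinct slots in the stopped schedule — the
examinations actually performed) and `draws` (in `with_replacement` mode,
duplicates included — the allocations an uninformed allocator would spend,
which can exceed the N × n slot budget).  Savings are defined against
`exams`: the percentage of *performed* examinations avoided at equal tdr,
`100 × (exams_RA − exams_strategy)/exams_RA`.  The two modes
(`with_replacement` / `without_replacement`) produce the same distribution
of stopped schedules and differ only in the draw count.

## Scenario grid

The default grid crosses dp ∈ {0.6, 0.3, 0.1}, cvmr ∈ {0.5, 0.25, 0.05},
r ∈ {0.2, 0.5, 0.8} (27 scenarios, numbered dp-major, r-middle, cvmr-minor)
at tdr targets {0.8, 0.9, 0.95}, with N = 5000 and 100 repetitions per
scenario.  Per repetition the three threshold rules are calibrated on the
same freshly drawn population on which RA is run; the RA reference averages
5 independent inner allocations.  Savings are computed per repetition and
averaged; the Monte-Carlo SE (sample SD / √reps) accompanies every mean.
All randomness derives from one root seed through named substreams
(trajectory / matrix / RA / events), so strategies always see identical
populations and adding a consumer never shifts another's stream.

## Cohort mode

Cohort mode replaces the generator with a table of per-patient predicted
annual risks plus optionally one observed event interval each, and defaults
to dp = 0.3, tdr 90%, examination sensitivity 80%.  Thresholds are
calibrated on the *predicted* risks (expected-occurrence accounting) — the
prospective-planner view — and the resulting schedules are then scored
against the observed events, each event at its interval midpoint
contributing its cascade detection probability.  Quintile summaries (by
cumulative 5-year risk, ties broken by patient order) report mean follow-ups
per patient and expected detections per quintile.

The synthetic cohort generator emulates the published moment structure of
INFLUENCE-nomogram predictions on a large breast-cancer cohort: lognormal
annual marginals (log-SD 1.0) around means (0.35, 0.68, 0.47, 0.44, 0.41)%,
a Gaussian copula whose lag-decaying latent correlations (0.8 linearly down
to 0.3, rescaled) imply a mean Spearman correlation of 0.61, and at most one
event per patient sampled sequentially with the conditional annual risks.
The published annual means (0.35 minimum, 0.68 maximum, 0.47 average,
coefficient of variation 0.24) are mutually consistent only under a
population (ddof = 0) CV, which `summarize_cohort` therefore reports; the
implied 5-year total is 2.35%.  What the generator does *not* emulate:
predictor-driven risk profiles (risks are exchangeable draws, not functions
of tumour characteristics), calibration error of a real nomogram, competing
mortality, or the event-year distribution of a registry population — so
cohort-mode results validate the machinery and orderings, not any specific
published count.

## Numerical choices and limitations

* Bisection tolerance 1e-8 risk units; detection comparisons exact to
  float64.
* Interpolated exam counts are real-valued by design; integer schedules are
  also emitted for per-patient summaries (at the lower-bracket threshold,
  which achieves at least the target).
* The framework assumes a single dp for everyone, no false positives, no
  dropout, no prediction error, and no mid-programme re-planning from exam
  results; all are out of scope.
* Savings depend on the RA examination count in the denominator and on the
  individual-spread scale `sigma_scale`; both conventions are recorded in
  every manifest so cross-study comparisons remain interpretable.
* Problem sizes used throughout (N = 5000, 100 repetitions, 5 RA inner
  runs) reproduce the study conditions; the grid at these sizes runs in a
  few minutes on one CPU because all accounting is exact and vectorised.
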