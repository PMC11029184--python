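# Methods

This note records the modelling choices behind `rsindex`: the scoring
system itself, the synthetic cohort the tests run on, and the numerical
conventions.

## Cohort construction

An episode enters the cohort when the patient was discharged **alive**
from the ICU and the hospital-episode outcome is known; palliative
discharges and transfers to other organisations are excluded
(`apply_inclusion_criteria` logs one count per exclusion reason).  The
outcome is the **first** occurrence of in-hospital death or ICU
readmission; later events are ignored (`link_outcomes` keeps the
earliest, with time-then-type tie-breaking so row order never
matters).  Each `admission_id` is a single episode ending at its first
event; a patient readmitted to ICU does not re-enter as a new post-ICU
episode.

Timestamps are integer minutes since an epoch; elapsed times are hours
as floats, because the fusion blend is parameterised in hours.
Observation sets recorded at or after the first event are retained in
storage; the evaluation layer censors them.

## RS₁ — static discharge risk

A logistic regression with an L1 penalty on the coefficients (the
intercept is never penalised) over the ICU-stay feature matrix.
Preprocessing belongs to the model: missing values are imputed with
the training median, features are z-scored with training means/SDs,
all-missing and zero-variance features are dropped with a warning, and
apply mode reuses the stored parameters only.  Optional per-feature
missingness indicators are off by default — median imputation is the
conservative default when the informativeness of missingness is
unknown.

The penalty per sample λ is chosen by **stratified 5-fold
cross-validated AUROC** (pick-the-max; no one-standard-error rule)
over 30 log-spaced values spanning four decades below the data-derived
λ_max — the smallest penalty whose solution is exactly null — so the
largest grid point always yields the null model.  Folds are seeded.
The final model is refitted on all data at the chosen λ (liblinear,
with the intercept refined to its exact conditional MLE by a Newton
step, so the L1 limit is the empirical-log-odds null model).  At the
L1 limit the model predicts the event rate for everyone; on separable
toy data it reaches in-sample AUROC 1.

The default feature spec is a plain data structure of 161
channel × operator × window entries (ward-style physiology, renal and
hepatic chemistry, electrolytes, inflammation markers, treatment
intensity, demographics) over the channels the synthetic generator
emits; users supply their own YAML spec for real data.  Only
per-channel summaries are generated — no interaction or transformation
terms.  Lab spread/trend features use whole-stay windows because
laboratory sampling is roughly daily.

## RS₂ — one-class vital-sign normality

The training set is every vital-sign set recorded on the **calendar
day of hospital discharge** of admissions that ended event-free — the
most defensibly "normal" ward physiology available without external
reference data.  Incomplete sets are dropped from training; at least
50 complete vectors are required; training is capped at 10 000 points
by seeded subsampling to bound scoring cost.

The density model is a product-Gaussian KDE over the five continuous
channels, z-normalised per channel, with per-channel Silverman
rule-of-thumb bandwidths h_j = sd_j · (4/((d+2)n))^(1/(d+4)) (the rule
is pluggable).  AVPU and supplemental O₂ are excluded from the
normality model — kernel density over mixed discrete/continuous data
is poorly determined — and remain available to the EWS comparators.

Novelty is −log density.  Missing channels are **marginalised**: the
product kernel factorises, so dropping the missing dimensions from
both kernel and probe yields the exact marginal density of the
observed channels.  RS₂ is the empirical-CDF position of the novelty
within the stored training novelty distribution (midpoint convention
for ties, clamped to [0, 1]).  This calibration makes RS₂ share a
scale with the probability-valued RS₁ so the two can be blended, and
makes RS₂ monotone in novelty by construction.

Scoring uses a BLAS-backed squared-distance expansion with a
log-sum-exp reduction; it matches a direct double-loop kernel sum to
better than 1e-10 relative error (tested), and the fitted density
integrates to 1 within quadrature error.

## RSI — the fusion

With τ = min(t, T_max)/T_max:  RSI = β(1−τ)·RS₁ + τ·RS₂.  The blend
is continuous and piecewise linear in t; beyond T_max, τ clamps at 1
and the score is RS₂ exactly — the static estimate's contribution is
designed to decay as the patient's condition evolves away from the
ICU-discharge state.

β and T_max are tuned by exhaustive grid search maximising mean
**patient-grouped** 5-fold cross-validated AUROC for the 24 h compound
outcome (no admission spans folds, respecting within-patient
correlation of repeated observations).  Ties break toward smaller β,
then smaller T_max.  Default grids: T_max ∈ {24, 48, 72, 96, 120, 168,
336} h (the post-ICU follow-up window is 14 days) and β ∈ {0.25 … 8}.
β's job is scale harmonisation: RS₁ is a probability with mean near
the event rate (≈ 0.09), while RS₂ is percentile-calibrated on [0, 1],
so the cross-validated optimum sits well above 1; capping the β grid
at ~2 would force the blend below the performance of RS₂ alone.

## EWS comparators

MEWS, SEWS, NEWS and CEWS are table-driven: per vital an ordered list
of closed [lower, upper] bands with non-negative integer points,
contiguous at chart precision (integers; 0.1 °C for temperature) and
covering the full plausibility range — the loader rejects gaps,
overlaps and negative points, which makes coverage checkable.  Band
files are transcribed from the primary publications (sources named
inside each YAML) and are user-replaceable; the CEWS table encodes the
centile scheme of its source chart (3 points beyond the 1st/99th
centiles, 2 for 1st–5th/95th–99th, 1 for 5th–10th/90th–95th) and is an
approximate transcription.  Missing components score 0 points under
the default policy (with a warning); a strict mode raises instead.
Each implementation is tested against an independently hand-coded
nested-conditional chart on a sampled grid of the full vital range.

## Evaluation framework

The unit of analysis is the vital-sign observation set.  For horizon
N, a set is positive iff the admission's first event of the chosen
endpoint (compound, death-only, or readmission-only) occurs in
(obs_time, obs_time + N]; sets at/after the first event of any type
are censored; everything else is negative.  Positives therefore nest
as N widens, and the three classes partition the observations —
both are tested invariants.  Event-free observations within N hours of
hospital discharge count as negatives by default
(`censor_near_discharge` enables the alternative).

* **AUROC**: Mann-Whitney rank form, ties counted ½; equal to
  brute-force pairwise counting to 1e-12 (property-tested).
* **Uncertainty**: percentile bootstrap, B = 500, resampling
  **admissions** (not observation sets) with replacement; 2.5/97.5
  percentiles; seed-deterministic.  Resamples on which the metric is
  undefined are skipped; more than 10% undefined is an error.
* **Calibration**: Hosmer-Lemeshow C over 10 equal-count risk groups
  (stable sort; groups with near-zero expected events are merged with
  a warning), Brier score, and Cox calibration regression — an
  unpenalised logistic refit of outcomes on logit(p) (probabilities
  clipped to [1e-6, 1−1e-6]); intercept α near 0 and slope β near 1
  indicate good calibration.  A zero-variance predictor leaves the
  slope undefined (NaN) rather than failing.
* **Trigger burden**: per threshold, triggered sets per correctly
  triggered pre-event set (per-TP-observation normalisation; infinite
  burden is flagged, not raised).
* **System comparison**: every system is evaluated on identical
  labelled sets; a shared label checksum per (horizon, endpoint) cell
  is the audit trail.

## The synthetic cohort generator

The generator emulates the study conditions the method assumes; it is
first-class, tested code.

* Each admission draws a latent severity z ~ N(0, 1); elective
  admissions (30%) get a −0.8 shift.  Event probability is
  sigmoid(α + 1.2·z_eff) with α solved (Brent) so the expected
  compound rate equals the configured readmission 6.6% + death 2.2%;
  the type split follows the configured ratio, and the event time is
  uniform over the ward episode within the 14-day follow-up.
* ICU channels (five vitals hourly with AR(1) noise, twelve labs
  roughly daily, ventilation/vasopressor/dialysis as on/off
  intervals) load on z; these loadings are the planted effects stored
  in the ground truth.  Elective admissions are ventilated until
  shortly before discharge, reproducing the clinically real pattern
  that ventilation in the last 24 h marks low-risk elective surgical
  patients.
* Ward vitals are patient-level Gaussian baselines near textbook
  normals (mildly loaded on z) plus AR(1) noise, sampled every
  U(4, 6) h, rounded to chart precision and clipped to plausibility
  bounds.  AVPU is Alert and supplemental O₂ has a 15% base rate.
* Deterioration is imposed retrospectively on event admissions: a
  linear drift (HR +25, RR +10, SBP −30, SpO₂ −8, temperature +1 at
  full strength) from onset to event, with AVPU decay and rising
  supplemental-O₂ probability.  The prodrome is deliberately
  heterogeneous — per-event lead U(4, 44) h and severity scaling
  U(0.3, 1.2) — because deterioration usually, but not always or
  uniformly, precedes adverse events; a uniformly florid prodrome
  would make ward vitals nearly sufficient and leave no complementary
  role for the static score, which is not the structure the method
  assumes.
* Determinism: one seed sequence spawns a global stream plus one
  stream per admission, so pre-onset observations are bit-identical to
  the event-free counterfactual under a shared seed (tested), and the
  whole cohort is reproducible from its seed.

What the generator does **not** emulate: site/case-mix differences
between hospitals, circadian rhythm, treatment response, correlated
missingness, post-event observations during ICU readmission, and any
decay of the latent risk's relevance over time.  Consequently RS₁
stays informative for the whole stay here, whereas on real data its
value decays — passing tests show the machinery is correct under the
assumed structure, not that these effect sizes transfer to real
cohorts, and discrimination figures published for real hospital
cohorts are not reproducible from synthetic data.

## Problem sizes and numerical conventions

The end-to-end demonstrations use 5000 admissions (≈ 190 000
observation sets); support-recovery checks use n = 2000 with 5
informative of 50 features across 20 seeds; calibration closed-form
checks use n = 10 000.  liblinear tolerance is 1e-5 with the Newton
intercept refinement; KDE scoring chunks probes (4096 per block) and
groups them by missingness pattern; fusion grid ties break toward the
smaller, simpler model.  All randomness flows from explicit seeds.

## Known limitations

* The exact one-class method and the RS₂ density→score mapping in the
  original system are configurable choices here (KDE + empirical CDF
  as the reference implementation; the bandwidth rule and band tables
  are pluggable/replaceable).
* SEWS and CEWS band values are transcriptions of their primary
  publications; users validating against a local deployment should
  supply their own band files.
* The evaluation treats repeated observations of one patient as
  exchangeable when pooling AUROC (the field's standard, with the
  bootstrap over admissions acknowledging the correlation); no mixed
  models are provided.
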