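# Methods

This note records the models implemented in `msprog`, the assumptions they
make, the defaults and why they were chosen, what the synthetic registry
does and does not emulate, and the numerical conventions that a maintainer
would otherwise have to reverse-engineer from the code.

## Disability classes and labels

EDSS (0–10 in 0.5 steps) is collapsed into three ordinal classes spanning
the conventional ambulation milestones: C1 (≤ 3.0), C2 (3.5–5.5), C3
(≥ 6.0). Labels come from a clinical registry of dated assessments;
relapse-flagged assessments are excluded because EDSS measured during a
relapse does not reflect the underlying disability level. Each patient is
labelled with the relapse-free assessment nearest to the end of their
6-month observation window; equidistant ties resolve to the earlier
assessment. Patients with no eligible assessment stay unlabelled but remain
in the cohort for whole-population inference.

## Cohort construction

Case-finding follows the claims-based convention for MS surveillance: a
patient qualifies with at least one MS-specific DMT prescription, one
hospital admission listing ICD-9-CM 340 anywhere among the discharge
diagnoses, or one outpatient encounter in an MS-specific service category
(default: rehabilitation; configurable, since regional coding habits
differ). The entry date is the earliest qualifying record. Non-residents
and patients missing sex or birth year are excluded, each reason counted
separately.

Features aggregate the half-open window `[entry, entry + 6 calendar
months)`; records on the window-end day do not count. Choices the source
conventions leave open, resolved here:

* **Therapy duration** is days covered within the window by the union of
  30-day dispensation intervals (not cumulative time since first DMT).
* **Platform→high-efficacy switch** is recorded iff some platform-tier
  dispensation strictly precedes some high-efficacy dispensation within the
  window.
* **Age** is window-start year minus birth year — administrative extracts
  rarely carry full birth dates.
* **Uncatalogued drug names** are warned about and counted in an `other`
  bucket rather than dropped (newer DMTs post-date any fixed catalogue).
* The severe-disability ICD-9 list defaults to {344.0, 344.1, 342.9}
  (quadriplegia, paraplegia, hemiplegia) and is user-configurable; it is a
  placeholder for a locally validated list, not a clinical claim.

## EDSS classifier

A 64-32-3 feed-forward network with ReLU hidden activations and softmax
output, trained with Adam (lr 0.001, batch 32), dropout 0.2 (training time
only, inverted scaling), L2 penalty 1e-4 (a value had to be fixed; 1e-4 is
a conventional mild weight decay), categorical cross-entropy (implied by
the softmax multi-class output), 10 epochs, on a stratified 70/30
train/validation split. Stratification guarantees all classes appear in
both splits at small n; a class that still cannot be split raises an error
rather than silently training on two classes. Continuous features are
standardised with training-split statistics only. Grid search (Cartesian,
validation accuracy, ties to the first point in lexicographic grid order)
covers learning rate, batch size and first-layer width; the default grid is
lr ∈ {1e-2, 1e-3, 1e-4}, batch ∈ {16, 32, 64}, width ∈ {32, 64, 128} — a
convention, since no canonical grid exists.

## Neural Cox progression model

The event is the first transition to any higher EDSS class; C3 is absorbing
and C3-labelled patients are excluded from the risk set. Times are months
from entry; follow-up ends at the last relapse-free assessment
(administrative censoring at study end propagates through the visit
schedule). Because clinic visits are ~6-monthly, onsets are
interval-censored; the sample builder imputes the midpoint between the last
assessment in the lower class and the first in the higher class, which
removes the upward bias a "first visit showing the higher class"
convention would add to every event time.

The risk network (32-32-16, ReLU, scalar output g(x)) minimises the
negative log Cox partial likelihood with the Breslow convention for tied
event times. Two non-obvious choices:

* **Full-batch training.** The partial likelihood couples each event to its
  whole risk set; mini-batches would evaluate risk sets on subsamples and
  bias the gradient. At the sample sizes involved (hundreds to thousands)
  full-batch Adam is also simply faster.
* **Tie handling is Breslow in both the loss and the baseline-hazard
  estimator**, keeping the training objective and the absolute-risk
  estimator consistent.

Early stopping: training halts when the per-event validation loss fails to
improve by 1e-4 for 10 consecutive epochs, restoring the best weights.
Evaluation uses five outer folds; each fold's 20% is the test subset and
the remaining 80% is split into training (60% of the total) and validation
(20%), stratified by event status. These two prescriptions (5-fold CV and a
60/20/20 split) are reconciled exactly this way because it preserves both
numbers. The deployed model is refit on all samples with an internal
stratified 80/20 early-stopping split, and carries the Breslow baseline
estimated from the full sample.

With no hidden layers the network is a linear Cox model, and its
coefficients (rescaled by the feature standard deviations) must agree with
a classical maximum-partial-likelihood fit — this is tested against
lifelines on simulated proportional-hazards data.

## Evaluation statistics

* **Classification**: accuracy, macro-averaged precision/recall/F1 (the
  macro choice is stated rather than assumed; per-class values are also
  emitted so a weighted reading can be reconstructed), per-class
  sensitivity/specificity, and 95% patient-level percentile-bootstrap CIs
  (default 1000 resamples, seeded).
* **Concordance**: Harrell's C implemented directly from its definition —
  pairs with a strictly earlier observed event are comparable; tied risks
  earn half credit. (lifelines' implementation additionally credits pairs
  with tied times, so it is used only as a tie-free cross-check in tests.)
* **Kaplan–Meier** wraps lifelines' product-limit estimator.
* **Integrated Brier Score**: IPCW weights from the Kaplan–Meier estimate
  of the censoring distribution, G(tᵢ⁻) for observed events and G(t) for
  at-risk subjects; subjects needing a weight where G = 0 are dropped from
  that time point with a warning. The default grid is 100 evenly spaced
  points between the first and last event time, integrated by trapezoid
  and normalised by the grid span. Cross-checked against scikit-survival.

## Risk stratification and projection

1-D k-means is solved **exactly** by dynamic programming over contiguous
partitions of the sorted values (optimal 1-D within-cluster-SS clusters are
contiguous), so the result is deterministic and provably optimal; restart
parameters are accepted for interface compatibility but inert. The
high-risk threshold is the smallest 5-year cumulative hazard assigned to
the top cluster — the cut is then attained by an actual patient value, which
a midpoint convention would not guarantee.

Cluster centroids are fitted on patients still able to progress (current
class C1/C2): "risk of class change" is undefined for the absorbing top
class, and C3 patients' features lie outside the survival-training support,
where the network's exp(g) can extrapolate to extreme values. Every
patient, including C3, is then assigned to the nearest centroid, so the
cluster label remains a total function of H₅.

The current class state at the projection reference (mid-2021 by default)
is estimated progression-consistently: the classifier scores the 6-month
windows opening each 1 January of the three most recent years and the
per-patient **maximum** class is taken — in a progression-only model the
highest class seen is the current one, and pooling windows sharply reduces
single-window misclassification (on the default synthetic registry, state
accuracy rises from ~0.85 to ~0.94). Clinical EDSS (relapse-free, within 12
months of the reference) overrides the classifier wherever available.

Transitions are restricted to the adjacent higher class within the 5-year
horizon, C3 absorbing. The default `expected` mode moves probability mass
p₅ = 1 − e^{−H₅} per patient (producing fractional Sankey flows); the
`threshold` mode instead moves exactly the patients at or above the
high-risk threshold. Neither is asserted as "the" convention — the mapping
from a risk threshold to projected flows is genuinely underdetermined — so
both ship. Patients entering after the reference year are not projected
(closed cohort).

## Synthetic registry

The generator emulates what the pipeline needs from a regional claims
linkage, not regional epidemiology:

* demographic marginals of an MS cohort (64% female, age 42.5 ± 13.5 at
  entry, truncated to 18–90) and an entry class mix of 9/62/29%;
* a progression-only latent trajectory: time to the next class drawn from a
  proportional-hazards model whose log hazard is linear in standardised
  age, sex and current class, exponential by default (configurable Weibull
  shape) so that a proportional-hazards fit can recover the parameters and
  five-year probabilities have the closed form 1 − e^{−λ·60}. The baseline
  rate (0.0188/month) and class weight are calibrated so the five-year
  progression probability from C1 is ≈ 0.68 and from C2 ≈ 0.58 — the scale
  of progression a regional MS cohort exhibits;
* utilisation whose intensity rises with the current latent class
  (admissions, admission length, MS-coded and emergency admissions,
  severe-disability codes, rehabilitation encounters, high-efficacy DMT
  share and platform→high switching), all scaled by a single
  `signal_strength` dial. **At the default signal_strength = 1 the classes
  are deliberately well separated** (classifier held-out accuracy ~0.83–0.86,
  progression-consistent state accuracy ~0.94): the end-to-end conservation
  checks are meant to test the projection machinery, and under a noisy
  classifier they would test classifier error instead. Values below 1
  emulate the noisier regime of real administrative data; 0 removes all
  class dependence, under which the classifier must perform at the
  majority-class rate;
* a clinical sub-registry covering 22% of case-findable patients with
  6-monthly EDSS assessments drawn from the latent class at the visit date,
  10% of visits relapse-flagged, and loss to clinical follow-up at
  0.002/month;
* linkage noise to exercise the exclusions: 3% non-resident, 5% missing
  demographics (the scale of missing-demographics exclusions such cohorts
  report), 2% with no records at all (must not be case-found), 10%
  untreated (case-findable only through admissions/outpatient records).

All randomness flows from one seed through per-table sub-streams;
identical configurations reproduce every table byte-for-byte.
`analytic_transition_table` computes the generator's own expected five-year
flows (true class at a reference date, true per-patient rates,
adjacent-only) as the ground truth the pipeline's projection is compared
against; it requires the exponential model, whose memorylessness makes the
remaining-time distribution independent of the reference date.

What the generator does **not** emulate — so passing tests say nothing
about these aspects of real data: relapsing–remitting EDSS fluctuation
(trajectories only move up), drug-level pharmacoepidemiology, seasonal or
calendar effects in utilisation, regional geography, diagnostic
misclassification, and informative censoring (clinic dropout is independent
of severity).

## Problem sizes and numerics

Default study sizes follow the emulated setting: ~5000–8000 patients, of
whom ~22% are labelled (~1000), yielding ~600 survival samples. The test
suite runs the full pipeline at n = 5000 and the oracle comparisons at
n = 2000. Degenerate inputs are rejected loudly: zero events (Cox loss
undefined), a class missing from a training split, fewer distinct values
than clusters, horizons beyond follow-up (clamped with a logged warning).
Log-sum-exp stabilisation is applied inside the partial likelihood.

## Known limitations

* The survival discrimination on the default registry is modest (C-index
  ~0.5–0.6) because the generator's covariate effects on the hazard are
  mild; the high-discrimination regime is exercised separately on
  strong-signal proportional-hazards data. Calibration (which drives the
  projection) is good in both regimes.
* exp(g) can extrapolate to large values for feature vectors far outside
  the survival-training support; this inflates the upper tail of H₅ for
  some patients and occasionally the high-risk threshold. Scores are not
  clipped — the behaviour is reported rather than hidden.
* The 6-month visit discretisation is handled by midpoint imputation, not a
  full interval-censored likelihood.
* Single "any upward transition" event model; no competing risks,
  time-varying covariates, or separate C1→C2 / C2→C3 hazards.
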