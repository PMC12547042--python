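# msprog

Population-level estimation of multiple sclerosis (MS) disability and
prediction of its progression from routinely collected administrative
healthcare data.

The Expanded Disability Status Scale (EDSS) requires a neurological
examination and lives in clinical records, so it is invisible to the
administrative databases that cover a whole region's healthcare use. This
package implements a surveillance pipeline that fills that gap for
epidemiologists and healthcare planners working with linked claims data:

1. **Case-finding and features** (`msprog.cohort_features`) — identify people
   with MS from linked prescription, hospital-discharge and outpatient
   tables ("at least one MS-specific record in any database"), apply
   residency / missing-demographics exclusions, and aggregate each patient's
   utilisation over a 6-month window from entry into a fixed feature vector
   (DMT categories and platform-to-high-efficacy switches, admission counts
   and lengths, ICD-9 340 MS-related admissions, outpatient service
   categories, severe-disability codes).
2. **EDSS classification** (`msprog.edss_net`) — a feed-forward network
   (64-32 hidden units, ReLU, softmax over the three classes EDSS ≤ 3.0 /
   3.5–5.5 / ≥ 6.0; Adam, lr 0.001, batch 32, dropout 0.2, L2, 10 epochs,
   stratified 70/30 split, optional grid search) trained on the sub-cohort
   whose EDSS is known from a clinical registry.
3. **Progression risk** (`msprog.neural_cox`) — a hybrid survival model: a
   32-32-16 ReLU network g(x) trained with the negative log Cox partial
   likelihood (Breslow ties, full-batch since risk sets are global), early
   stopping on validation loss, and five outer folds with 60/20/20
   train/validation/test splits. The Breslow baseline cumulative hazard
   H₀(t) = Σ_{tᵢ≤t} dᵢ / Σ_{j∈R(tᵢ)} e^{g(xⱼ)} turns scores into absolute
   risk: H(t|x) = H₀(t)·e^{g(x)}, S(t|x) = e^{−H(t|x)}. Evaluation uses
   Harrell's C-index, the IPCW Integrated Brier Score and a Kaplan–Meier
   benchmark overlay.
4. **Stratification and projection** (`msprog.risk_projection`) — the
   classifier is applied to the whole population per calendar year; each
   patient's 5-year cumulative hazard H₅ (and progression probability
   p₅ = 1 − e^{−H₅}) feeds an exact 1-D k-means into low/moderate/high risk
   groups with a high-risk threshold, and class transitions are projected
   five years ahead (adjacent-class, progression-only, expected-mass flows)
   as a Sankey-ready table.
5. **Synthetic registry** (`msprog.synthetic_registry`) — regional registry
   data of this kind cannot be shared, so a seeded generator produces linked
   synthetic tables with the marginals such a cohort exhibits (~64% female,
   age ≈ 42.5 ± 13.5, class mix ≈ 9/62/29%, a ~22% clinical sub-registry)
   and a known proportional-hazards progression process, making every stage
   testable end to end against analytic ground truth.

## Worked example

```python
import numpy as np
import msprog as mp

cfg = mp.SimConfig(n_patients=2000, seed=42)
res = mp.run_pipeline(cfg)

r = res.exclusion_report
print(f"included patients: {r['n_included']} (case-found {r['n_case_found']}, "
      f"non-resident {r['excluded_non_resident']}, "
      f"missing demographics {r['excluded_missing_demographics']})")
print(f"labelled sub-cohort: {len(res.labels)}")
acc = res.classification_metrics["accuracy"]
lo, hi = res.classification_metrics["ci95"]["accuracy"]
print(f"classifier accuracy: {acc:.2f} (95% CI {lo:.2f}, {hi:.2f})")
print(f"survival model: C-index {res.survival_metrics['c_index']:.2f}, "
      f"IBS {res.survival_metrics['ibs']:.2f}")
print(f"high-risk threshold (5-year cumulative hazard): {res.threshold:.2f}")
cur, proj = res.transitions.current_marginals, res.transitions.projected_marginals
print(f"2021 class mix: {np.round(cur * 100, 1)}")
print(f"projected 2026 class mix: {np.round(proj * 100, 1)}")
print(f"share of C1 expected to progress to C2 by 2026: "
      f"{res.transitions.matrix[0, 1] / cur[0] * 100:.1f}%")
```

prints (numbers from this exact run):

```
included patients: 1800 (case-found 1962, non-resident 66, missing demographics 96)
labelled sub-cohort: 394
classifier accuracy: 0.87 (95% CI 0.82, 0.92)
survival model: C-index 0.55, IBS 0.22
high-risk threshold (5-year cumulative hazard): 1.13
2021 class mix: [ 0.2 29.4 70.4]
projected 2026 class mix: [ 0.1 15.1 84.8]
share of C1 expected to progress to C2 by 2026: 44.4%
```

Reading the output: of 1962 case-found patients, 1800 survive the
exclusions; the classifier recovers the three EDSS classes of the labelled
sub-cohort with 0.87 held-out accuracy; the survival C-index of 0.55
reflects the generator's deliberately mild covariate effects on the hazard
(age, sex and class shift the progression rate only moderately — see
`docs/methods.md`); patients whose predicted 5-year cumulative hazard
exceeds 1.13 form the high-risk cluster; and the transition table projects
the 2021 class mix five years forward under expected-mass flows.

The same stages are available from a shell:

```bash
msprog simulate --out data/ --seed 42
msprog build-cohort --in data/ --out cohort/
msprog train-classifier --features cohort/features.csv --labels cohort/labels.csv --out clf.bin
msprog train-survival --features cohort/features.csv --samples cohort/survival_samples.csv --out surv.bin
msprog project --classifier clf.bin --survmodel surv.bin --features cohort/features.csv --out report/
```

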