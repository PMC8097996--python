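# rwsurf — regularized and weighted random survival forests

`rwsurf` is a research tool for survival risk modelling in diabetes from
visit-to-visit biomarker variability. It is aimed at biostatisticians and
clinical-epidemiology groups who have longitudinal laboratory data (serial
HbA1c and lipid panels) and a right-censored outcome (all-cause mortality
or a diabetic complication) and want a tree-ensemble model that goes beyond
the proportional-hazards assumption while remaining interpretable.

## The model

A random survival forest (RSF) grows `B` survival trees on bootstrap
samples, splitting nodes by the two-sample log-rank statistic and storing a
Nelson–Aalen cumulative hazard H_b(t | x) in each leaf. A plain RSF
averages the trees uniformly. `rwsurf` instead treats the trees as
heterogeneous and learns a convex weight vector `w` on the simplex
(w_b ≥ 0, Σ w_b = 1):

    H_w(t | x) = Σ_b w_b · H_b(t | x)

by minimizing an L2-regularized discrete-hazard negative log-likelihood

    L(w) = (1/n) Σ_i [ −δ_i · log ΔH_w(t_i | x_i) + H_w(t_i | x_i) ] + λ Σ_b w_b²

with projected-gradient descent, where δ_i is the event indicator and
ΔH_w is the weighted hazard increment at the record's event time. The
regularization strength λ is chosen by five-fold cross-validation; as
λ → ∞ the weights return to uniform and the model collapses exactly to the
plain RSF. A patient's scalar risk score ("ensemble mortality") is the
ensemble cumulative hazard summed over the event-time grid.

Around the model, the package provides:

- **Feature engineering** — per-analyte baseline / temporal mean / SD /
  CV (= 100·SD/mean) from serial labs with a ≥3-measurement eligibility
  rule, hypoglycemia counting (glucose < 3.9 mmol/L), neutrophil–lymphocyte
  ratio, anemia and iron-deficiency flags, and `-1` padding of missing
  values with an explicit missingness mask.
- **Synthetic cohorts** — a generator of longitudinal labs plus Weibull
  proportional-hazards outcomes driven by *latent* patient-level means and
  volatilities, so parameter-recovery and discrimination claims can be
  tested against known ground truth.
- **Interpretation** — out-of-bag permutation importance under a
  fixed-horizon squared loss, minimal-depth rankings, and decision-rule
  extraction from the highest-weight tree.
- **Evaluation** — Harrell's C-index, precision/recall/AUC, stratified
  k-fold cross-validation against unweighted-RSF and Cox baselines.

## Worked example

```python
import pandas as pd
from rwsurf import (CohortSpec, simulate_cohort, build_feature_matrix, pad_missing,
                    make_survival_data, fit_rwrsf, RWRSFConfig, predict,
                    harrell_cindex, importance_report)
from rwsurf.synthetic import BASELINE_DATE, DAYS_PER_YEAR

cohort = simulate_cohort(CohortSpec(n_patients=500, seed=7))
window = (BASELINE_DATE - pd.Timedelta(days=round(5 * DAYS_PER_YEAR)), BASELINE_DATE)
matrix = build_feature_matrix(cohort.labs, cohort.baseline, window)
data = make_survival_data(pad_missing(matrix).frame, cohort.outcomes)

model = fit_rwrsf(data, RWRSFConfig(n_trees=100, seed=7))
print("lambda:", model.lambda_reg)
print("C-index (training):",
      round(harrell_cindex(predict(model, data.X).mortality, data.time, data.event), 3))
```

prints

```
lambda: 10.0
C-index (training): 0.899
```

The selected λ = 10 says the cross-validated likelihood preferred weights
close to uniform on this cohort (individual trees do not differ enough for
aggressive reweighting to pay off — the expected outcome when all trees
see the same modest signal). The training-set C-index of 0.90 is
optimistic, as training metrics always are for forests; held-out
discrimination for the same conditions is near 0.6, against a
ground-truth ceiling (the concordance of the true linear predictor) of
about 0.61 — see the reproduction script below.

The same pipeline runs from the shell:

```bash
rwsurf simulate --n-patients 500 --seed 7 --out-dir cohort/
rwsurf -v run --config config.yaml       # simulate -> features -> fit -> interpret -> evaluate
```

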