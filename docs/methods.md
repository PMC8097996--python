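# Methods

## Survival model

Each base learner is a survival decision tree for right-censored data.
Records carry a follow-up time in days (from the baseline date to event
or study end), an event indicator, and a fixed-length numeric feature
vector in which missing covariates have been padded to −1 (the padded
value routes through splits like any number, so missingness becomes a
learnable category on the left flank of every threshold; the mask is
retained separately for diagnostics).

**Splitting.** At each node, `mtry` features are sampled without
replacement (default ⌈√p⌉) and for each feature up to
`n_split_candidates` thresholds (default 10) are drawn from the unique
in-node values; the exhaustive scan is retained as an option and used by
the oracle tests. Candidates are scored with the standardized two-sample
log-rank statistic |O − E|/√V with the hypergeometric variance term and
tie-inclusive risk sets (censorings at t remain at risk for events at t).
A split is admissible only if each child would retain at least
`min_leaf_events` events (default 3); growth also stops at `max_depth`
(default 20) or when a node holds fewer than `2·min_leaf_events` events.
Zero-variance configurations score 0 and are never selected, so
degenerate inputs yield a single-leaf tree. Ties at a threshold route
left (x ≤ t).

**Leaves.** Each leaf stores the Nelson–Aalen cumulative hazard of its
members, H(t) = Σ_{t_k ≤ t} d_k/Y_k over the distinct event times, as a
right-continuous step function that is 0 below its grid.

**Ensemble.** `B` trees (default 100) are grown on bootstrap samples of
size n with replacement; out-of-bag (OOB) membership is recorded. The
ensemble cumulative hazard is the convex combination
H_w(t|x) = Σ_b w_b H_b(t|x) on the global grid of distinct training event
times; the scalar risk score ("mortality") is Σ_k H_w(t_k|x). Weights
are constrained to the probability simplex so the ensemble CHF remains a
valid non-decreasing hazard; uniform weights reproduce the plain RSF
average bit for bit.

## Weight learning

The weights minimize a discrete-hazard negative log-likelihood plus an
L2 penalty:

    L(w) = mean_i [ −δ_i log(ΔH_w(t_i|x_i) + ε) + H_w(t_i|x_i) ] + λ‖w‖²

where ΔH_w is the ensemble increment at the largest grid time ≤ t_i and
ε = 10⁻¹² floors increments that are exactly zero (a patient whose event
precedes the leaf's first event time would otherwise make the loss
infinite). This likelihood was chosen because it is computable from
exactly what the trees store; a Cox partial-likelihood alternative over
the mortality score is available behind `loss="cox"`.

Optimization is projected gradient descent from the uniform start with a
sort-based Euclidean simplex projection and a backtracking line search,
so the penalized objective is non-increasing along the iterate sequence;
it stops when the unit-step projected-gradient displacement falls below
10⁻⁶ or after 500 iterations. The deterministic optimizer keeps weight
learning reproducible independent of any seed; seeds only enter fold
assignment.

λ is selected from the grid {0, 10⁻³, 10⁻², 10⁻¹, 1, 10} by five-fold
cross-validation of the *unpenalized* held-out loss on the training
records, ties resolved toward the larger (more regularized) value. As
λ → ∞ the penalty dominates and its simplex minimizer is uniform, so the
model degrades gracefully to the plain RSF — this limit is verified to
10⁻³ per component in the tests. Weight learning uses the in-bag
aggregate (all training records); OOB records are reserved for error
estimation and importance.

## Feature engineering

Variability analytes are HbA1c, total cholesterol, HDL-C, LDL-C and
triglyceride. Per patient and analyte, measurements inside the lookback
window yield: baseline (earliest in-window value), temporal mean,
temporal SD, and CV = 100·SD/mean. The SD uses the n−1 denominator (the
convention of the biomarker-variability literature). A patient is
eligible for the variability statistics of an analyte only with ≥3
in-window measurements; otherwise mean/SD/CV are missing while the
baseline value is kept. CV is set missing when the mean is zero (cannot
occur for physiological values but must be defined).

Clinical flags: a hypoglycemia episode is a glucose reading strictly
below 3.9 mmol/L; anemia is hemoglobin < 13 g/dL (male) / < 12 g/dL
(female), strict; iron deficiency is ferritin < 67.4 pmol/L, strict;
NLR is the baseline neutrophil count over the baseline lymphocyte count,
missing when the denominator is zero. Hypoglycemia episodes are counted
inside the lookback window by default: counting over the whole follow-up
would place post-baseline information inside a baseline predictor, so
the leaky whole-follow-up mode exists only behind an explicit switch.
A missing input always yields a missing flag, never a False one.

## Synthetic cohort generator

The generator emulates an insulin-treated diabetic registry cohort. Per
patient i and analyte a it draws a latent mean μ_ia ~ Normal(population
mean, between-patient SD) and a latent volatility σ_ia ~ LogNormal
(parametrized by its mean and SD); visit counts are negative binomial
(mean 10, dispersion 4, truncated at ≥1) with dates uniform over a
5-year lookback; measurements are μ_ia + σ_ia·ε with standard normal ε,
clipped at a physiological floor. Default magnitudes: HbA1c mean 8.56%
with mean within-patient SD 1.28 (SD of the volatility 0.85), lipids at
typical mmol/L levels; the triglyceride within-SD is set to ≈0.57, the
value consistent with a CV of ~31% at mean 1.86 mmol/L (SD and CV of a
positive biomarker cannot disagree, so the CV anchors the default), and
the LDL-C population mean is 2.78 mmol/L.

Outcomes follow a Weibull proportional-hazards model: with linear
predictor η built from *latent* features (centered at their population
values), the event time is scale·(−log U · e^(−η))^(1/shape) by inverse
transform, with shape 1.1 and scale 5757 days so that ~49% of a null
cohort dies within the 11-year administrative horizon. Censoring is
administrative only by default (a fixed study end); exponential dropout
is available behind a flag. Default log-hazard coefficients follow the
magnitudes of multivariate mortality hazard ratios in such cohorts: age
0.039/yr, male 0.166, HbA1c mean 0.086, HbA1c SD 0.095, HDL-C mean
−0.506, HDL-C SD 0.784, NLR 0.0149.

Because the hazard is driven by the latent values, not their noisy
estimates, recovery tests are meaningful: the estimated temporal SD
should correlate with the true σ (Spearman > 0.8 at ≥10 visits), and the
concordance ceiling of any fitted model is the C-index of the true
linear predictor (~0.61 under the defaults). What the generator does
*not* emulate: visit-process informativeness (sicker patients measured
more often), measurement drift and trends, coded comorbidity onset,
drug-dose trajectories, or competing risks. Tests passing on these
cohorts therefore establish internal correctness and qualitative
behavior, not registry-scale discrimination: a registry model with rich
comorbidity covariates can reach C ≈ 0.88, while these synthetic
conditions cap all models near 0.6 by construction.

## Interpretation

**VIMP.** The prediction error is a fixed-horizon squared loss between
1 − S_w(horizon|x) and the observed status at the horizon (default
horizon: median follow-up), restricted to records determinable at the
horizon — an event before it, or follow-up past it. This restriction
avoids the bias a naive squared loss incurs from censored-before-horizon
records while keeping the null centered at zero; an IPCW variant was
considered and left out of the default because the restriction is
simpler to reason about and the importance *ranking* is the deliverable.
Each record is predicted only by its OOB trees with the forest weights
renormalized over them. VIMP = permuted-column error − baseline error,
with one permutation per feature from a seeded generator; zero or
negative values mark non-predictive features.

**Minimal depth** is the depth of a feature's first split averaged over
trees, with unused features contributing that tree's realized maximum
depth + 1 (the convention of the minimal-depth literature). It depends
only on forest structure, never on the weights.

**Rules.** Decision rules are extracted from the highest-weight tree
(the natural reading of a "main tree" in a weighted ensemble):
root-to-leaf paths are simplified to one binding bound per feature and
direction, ranked by leaf mortality, and annotated with OOB member
counts and event fractions.

## Evaluation

Harrell's C-index counts pairs (i, j) with t_i < t_j and δ_i = 1;
concordance means the earlier failure has the higher risk, risk ties
credit 0.5. Precision and recall are reported at an explicit operating
point — predicted-positive = risk at or above the cohort median — since
a survival risk score has no intrinsic threshold; AUC is the rank-based
two-sample statistic with the whole-follow-up event indicator as label.
Cross-validation stratifies folds by the event indicator to stabilize
small-fold metrics. Within each fold the weighted and unweighted forests
share the same trees (uniform vs learned weights), isolating the
contribution of the weighting itself; the Cox baseline is a
partial-likelihood fit with Breslow ties (Efron was not needed at the
precision of the comparisons here) and is scored by its linear
predictor. All metrics are invariant to monotone transforms of the risk
scores.

## Numerical and design notes

- Problem sizes in the test-suite and reproduction script (n = 500–1000,
  B = 100, 5–10 seeds) were chosen as the smallest at which the
  stochastic properties under test (signal recovery, non-inferiority)
  are stable across seeds.
- Tied event/censoring times use the standard at-risk convention;
  duplicated datasets leave Cox coefficients and all rank metrics
  unchanged.
- The forest's global grid is the set of distinct training event times;
  each tree's leaf CHFs are cached on this grid after fitting, making
  likelihood evaluations matrix products.
- Determinism: every stochastic step (bootstrap, feature/threshold
  sampling, fold assignment, permutations, simulation) flows from an
  integer seed through spawned NumPy generators; re-running a pipeline
  config reproduces byte-identical artifacts.
- Known limitations: no competing risks, no time-varying covariates, no
  honest-forest split of estimation and structure samples; the
  importance horizon treats status as binary and ignores late events
  beyond it.
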