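# voxelsurv

Leakage-free multi-site survival risk modelling from voxel-based
structural MRI and clinical variables.

## The problem

Clinical teams following patients after a first episode of psychosis want
to know, at baseline, who is at high risk of relapse: those patients may
benefit from closer follow-up, while low-risk patients may be receiving
unnecessary prophylactic treatment. The available predictors are
voxel-based morphometry (VBM) maps — unmodulated/modulated gray- and
white-matter images in a common template space — plus clinical scale items
(PANSS, GAF, MADRS, YMRS), diagnosis and treatment flags, from patients
recruited at several hospitals with different scanners. The outcome is a
right-censored time to relapse.

`voxelsurv` implements the full modelling pipeline for this setting:

* **ComBat site harmonization** with strict train/test separation: all
  parameters (feature-wise standardization, empirical-Bayes per-site
  location γ* and scale δ*) are estimated on training subjects only and
  applied frozen to held-out subjects;
* age/sex **residualization** of the imaging features and **[0, 1]
  scaling** of clinical variables, likewise train-fitted and frozen;
* an **L1-penalized ("lasso") regression** for Cox (Breslow partial
  likelihood), gaussian and binomial families —
  `min −(2/n)·pl(β) + λ‖β‖₁` — with λ chosen by internal cross-validation
  (Verweij–van Houwelingen deviance for Cox);
* **subject-bootstrap and half-brain voxel ensembles** (18 members by
  default) whose per-subject linear predictors are averaged;
* a subject is flagged **high relapse risk (HRR)** iff the linear
  predictor `Σ β̂_j x_j` is positive (hazard ratio > 1);
* **event-stratified k-fold cross-validation** with every data-derived
  transform fitted inside the training split, and a **site-aware Cox
  evaluation** of the resulting risk groups (Gaussian site random
  intercept, stratified fallback), Kaplan–Meier curves, voxelwise
  survival maps, and Schoenfeld power calculations.

A fully-specified synthetic cohort generator (multi-site volumes with
planted signal clusters, covariate effects, scanner effects, and
exponential relapse times censored at 24 months) makes every stage
testable against known ground truth. See `docs/methods.md` for the model
and all numerical choices.

## Worked example

```python
import numpy as np
from voxelsurv import RiskModel, PipelineConfig, SyntheticSpec, generate_cohort

cohort = generate_cohort(SyntheticSpec(seed=1))     # 240 subjects, 2 sites
model = RiskModel.from_cohort(cohort, PipelineConfig(seed=1))

cv = model.cross_validate()                         # leakage-free, 10 folds
print(cv.summary())
```

Output (as printed by the code):

```
Cross-validated risk estimation
  folds    : 10
  subjects : 240 (0 excluded)
Risk-group Cox comparison (HRR vs low risk)
  method          : stratified
  HR              : 3.314  (95% CI 1.359 - 8.081)
  Z               : 2.635   P = 0.0084
  site variance   : 0.0000
  n (HRR / low)   : 138 / 102
  events (HRR/low): 25 / 6
```

Reading this: out-of-fold risk estimates put 138 of 240 subjects in the
high-relapse-risk group; their observed hazard of relapse is ~3.3 times
the low-risk group's (site-aware Cox, P = 0.008), so the pipeline
recovered the planted risk factor from held-out data. A full-data fit and its sparse
coefficient table (with voxel mm coordinates) come from `model.fit()` /
`.summary()`; `voxelsurv.kaplan_meier` and
`voxelsurv.voxelwise_survival_map` provide the survival curves and
univariate brain maps.

A thin CLI mirrors the library: `voxelsurv simulate | fit | cv | predict |
compare` (see `voxelsurv --help`).

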