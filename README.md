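# megstrat

Differential stratification of four participant groups — PTSD, trauma-exposed
controls (TC), mild traumatic brain injury (mTBI), non-trauma controls (NTC) —
from MEG-like source-space recordings, using two neural feature families and a
nested-CV feature-selection/classification pipeline.

PTSD and mTBI present with heavily overlapping symptom profiles, which makes
differential diagnosis from questionnaires unreliable; resting-state neural
activity offers objective markers. This package implements the downstream
informatics for that problem, for researchers who have (or want to simulate)
per-subject ROI time series:

* **Regional band power** — Welch PSD per 10 s epoch per ROI, epoch-averaged,
  integrated over the seven canonical bands (delta 1–3, theta 4–7, alpha 8–14,
  beta 15–30, low gamma 30–55 and 65–80, high gamma 80–150 Hz): 90 features
  per band at study scale.
* **Amplitude envelope correlation (AEC) connectomes** — band-pass, optional
  pairwise leakage orthogonalisation, Hilbert envelope, slow-envelope Pearson
  correlation, Fisher-z epoch averaging: 90·89/2 = 4005 edges per band.
* **CV-SVM-rRF-FS** — stratified 85/15 holdout; within the training data, a
  stratified 10-fold outer loop runs an (optional) training-only univariate
  raw-p screen, recursive random-forest feature elimination with a
  one-standard-error stopping rule, and per-fold SVM scoring; features
  selected in ≥50% of folds form the consensus set for the final tuned SVM
  (linear/RBF, inner-CV grid). PLS-DA re-checks the consensus independently,
  and a sample-label permutation test with p = (1 + #{perm ≥ obs})/(1 + n_perm)
  guards against chance-level models. Per-group performance is one-vs-rest
  accuracy (%) and ROC-AUC on the untouched holdout.
* **Synthetic cohorts** — since clinical recordings of this kind are not
  publicly deposited, a generator produces four-group cohorts of 1/f noise
  plus band-limited oscillations with slowly varying envelopes, realistic
  between-subject variability, and plantable ground truth (regional power
  elevations, envelope couplings), so the whole chain is testable end to end.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The `analysis/` scripts run the chain at a reduced desk scale (80 subjects,
20 regions, alpha band, 128 Hz, 6 × 10 s epochs) with the standard planted
ground truth: three regional alpha power elevations (amplitude ×2.0) marking
PTSD, mTBI and TC, and two alpha envelope couplings (0.6) marking PTSD and
mTBI+TC:

```bash
python analysis/01_simulate.py --seed 0     # cohort + ground truth
python analysis/02_features.py              # power + AEC feature CSVs
python analysis/03_univariate.py            # standalone FDR analysis, clustering, PCA
python analysis/04_select_and_train.py      # CV-SVM-rRF-FS + final SVM + PLS-DA
python analysis/05_evaluate_holdout.py      # permutation test + holdout scoring
```

Output of the univariate stage (seed 0):

```
power: 3 / 20 features FDR-significant at alpha=0.05; 3 pass the raw-p reduction
aec: 4 / 190 features FDR-significant at alpha=0.05; 18 pass the raw-p reduction
```

Only a handful of features survive FDR — univariate tests alone are weak
here — yet selection and modelling succeed (seed 0):

```
power: mean CV 4-class accuracy 0.514; consensus 3 features: ['pow_alpha_2', 'pow_alpha_5', 'pow_alpha_8']
  PLS-DA check: CV accuracy 0.603, permutation p = 0.010
aec: mean CV 4-class accuracy 0.662; consensus 4 features: ['aec_alpha_10_11', 'aec_alpha_13_14', ...]
power: permutation p = 0.010
  holdout per-group accuracy (%): {'NTC': 75.0, 'PTSD': 83.3, 'TC': 91.7, 'mTBI': 83.3}
  holdout one-vs-rest AUC: {'NTC': 0.667, 'PTSD': 0.963, 'TC': 1.0, 'mTBI': 0.889}
```

Reading this: the power-only model's consensus is exactly the three planted
power ROIs; the AEC model's consensus contains both planted edges. Permutation
p = 0.010 (99 permutations) means no label shuffle matched the observed CV
score. Holdout percentages are one-vs-rest accuracies over the 12 held-out
subjects (chance baseline ≈75% for four balanced groups, so NTC at 75% is
uninformative while TC at 91.7% is a real signal — each feature family alone
carries only part of the planted structure; combining both recovers all five
planted features and pushes every group above 70%, which is what the
acceptance suite asserts over ten replicates).

A `megstrat` CLI (`simulate`, `features`, `select`, `report`) wraps the same
library for config-file-driven runs.

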