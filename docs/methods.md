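# Methods

This package reimplements, as tested reusable code, a downstream analysis
chain for differential stratification of four participant groups — PTSD,
trauma-exposed controls (TC), mild traumatic brain injury (mTBI) and
non-trauma controls (NTC) — from source-space MEG-like recordings: 90-region
"virtual sensor" time series segmented into 10 s epochs. Because raw clinical
recordings of this kind are not publicly deposited, the chain is exercised
end to end on a synthetic cohort generator with plantable, known ground
truth. This note records the model, the parameter choices that matter, and
what the synthetic experiments do and do not establish.

## Synthetic cohort model

Each ROI channel of each epoch is

    x(t) = s · n_1/f(t) + Σ_b a_b · e_b(t) · sin(2π f_b t + φ)

with 1/f^α background noise `n` (power-law exponent α, default 1.0;
standardised to SD `s`, default 1.0), band amplitudes `a_b`, carriers at the
band centre frequency with a uniform random phase per (epoch, region, band),
and slowly varying positive envelopes `e_b(t) = max(1 + d·z(t), 0)` where `z`
is a standardised Gaussian process with spectral content below 1 Hz
(white noise on a 2 Hz grid, linearly interpolated) and `d` is the
modulation depth (default 0.5).

Ground-truth effects:

* **power** — multiplies `a_b` in target ROIs for target groups. A magnitude
  of 2.0 doubles the amplitude and hence quadruples band power.
* **edge** — mixes the two target ROIs' slow processes with a shared one,
  `z_i ← √c·g + √(1−c)·z_i`, so the envelope correlation of the pair is ≈ c
  and the envelopes are identical at c = 1.

Between-subject variability, without which classification would be
degenerate (a single noiseless marker would separate groups perfectly and
parsimony-driven selection would discard every redundant feature), is
modelled by four fixed, realistic sources chosen once:

* a global per-subject amplitude factor, log-normal σ = 0.2 — individuals
  differ in overall source power;
* independent per-(band, region) amplitude factors, log-normal σ = 0.3 —
  regional band power varies between subjects beyond any group effect
  (together these put a magnitude-2.0 power effect at roughly d ≈ 1.5–2 on
  the log-power scale: a moderate, not trivial, marker);
* per-subject jitter of each planted coupling coefficient, SD = 0.25
  (clipped to [0, 1]) — connectivity strength varies between individuals;
* a per-subject global envelope co-modulation (arousal-like), coefficient
  ~ N(0.15, 0.10) clipped to [0, 0.9], shared by all regions — it raises
  baseline AEC for every pair and adds correlated between-subject variance
  to all edges.

With these defaults the planted markers land in the moderately strong
univariate regime (one-way F roughly 10–40 at n = 80), mirroring a setting
in which single features are rarely decisive but multivariate selection
succeeds. What the generator does **not** emulate: spatial leakage from
source reconstruction (beyond what pairwise orthogonalisation is tested
against), non-sinusoidal waveforms, cross-frequency coupling, artefacts,
and site/age covariates. Passing recovery tests therefore show the
*pipeline* behaves correctly under a realistic effect-and-noise geometry;
they are not evidence about real clinical MEG.

Sampling defaults are 600 Hz (so the 80–150 Hz band is resolvable) with 12
epochs; both are configurable, and all reduced-scale analyses here use
lower rates that still resolve the bands they generate. Determinism: all
randomness flows from one master seed via `numpy` SeedSequence spawning;
identical (config, effects, seed) give bit-identical cohorts.

## Feature derivation

**Regional power.** Welch PSD per 10 s epoch per ROI (2 s Hann segments,
50% overlap — 0.5 Hz resolution, enough for the 1–3 Hz delta band), averaged
across epochs; band power is the trapezoidal integral over the band. Powers
are stored as log10 absolute band power (toggleable): the log tames the
strong right skew of power across subjects. 90 regions × 7 canonical bands
(delta 1–3, theta 4–7, alpha 8–14, beta 15–30, low gamma 30–55 and
65–80, high gamma 80–150 Hz).

**AEC connectivity.** Per epoch: zero-phase 4th-order Butterworth band-pass
(≈48 dB/octave after forward–backward filtering), optional pairwise
symmetric leakage orthogonalisation (each signal residualised on the other,
directed correlations averaged; default ON), Hilbert envelope, low-pass
smoothing of the envelope at 1 Hz with decimation to ~4 Hz (envelope
dynamics are slow; this cuts cost without losing signal), Pearson
correlation. Epoch matrices are averaged on the Fisher-z scale and
back-transformed, so stored values remain correlations. The 90-region
connectome vectorises to 90·89/2 = 4005 edges in canonical i<j order.

Numerical details: correlations of zero-variance envelopes are defined as
0; a residual that is pure numerical roundoff (near-collinear pair) is
treated as carrying no signal, so a channel's AEC with its own copy is 0
under orthogonalisation rather than an artefact of roundoff noise. At
10 s × 10 epochs an individual null edge has sampling SD ≈ 0.07 (the slow
envelope offers only ~10–20 effective samples per epoch); unbiasedness is
therefore asserted on the mean across edges, not per edge.

## Univariate screening and exploratory views

One-way four-group ANOVA per feature (Kruskal–Wallis available); constant
features degenerate to p = 1 with a warning. Benjamini–Hochberg step-up
FDR across features (alpha 0.05) for the standalone analysis. The two-step
pipeline instead thresholds raw p < 0.05 (the level is a package default;
it is deliberately liberal since this step only reduces compute) — fitted
strictly on training subjects, with an explicit leakage check that refuses
holdout ids in the input. Z-scoring for the clustering/PCA views uses
training-partition statistics only. Clustering: Ward/Euclidean over
subjects, average/correlation over features; agreement with true groups is
reported as adjusted Rand index.

## CV-SVM-rRF-FS

Outer loop: stratified 10-fold CV over the training partition (the 15%
holdout is removed first and guarded by a partition digest). Per fold:

1. optional raw-p screen on the fold's training part (two-step mode);
2. recursive random-forest elimination: at each size, forests fitted on the
   3 inner-CV training folds give both the held-out error and the
   fold-averaged impurity-decrease importances (more stable than a single
   full-data fit); the lowest-importance 20% of remaining features is
   dropped per round (ties broken by fixed feature order), and the smallest
   subset within one standard error of the minimum error is returned;
3. SVM tuning by 3-fold inner CV over {linear, RBF} kernels with log-spaced
   C ∈ {0.1, 1, 10, 100} and γ ∈ {scale, 0.01, 0.1, 1}; the grid is ordered
   linear-first with ascending C so accuracy ties resolve toward the more
   parsimonious model. Class weights are inverse to group size.

Defaults: 500 trees (reduced-scale analyses here use 100 — at ≤ a few
hundred candidate features after screening, rankings are stable well below
500 trees), minimum subset size 2, consensus = selected in ≥ 50% of outer
folds. The final SVM is tuned and fitted on all training data restricted to
the consensus features. An empty consensus is an explicit "no-model"
outcome, reported rather than silently skipped.

**PLS-DA verification.** Partial least squares on a one-hot response
(3 components by default), CV accuracy by argmax of predicted responses,
and a label-permutation p-value. p ≥ 0.05 raises an `svm_only` flag: the
consensus features discriminate under the SVM but not under this
independent linear classifier.

## Evaluation

* **Split:** stratified 85/15 with largest-remainder per-group rounding and
  ≥1 holdout subject per group.
* **Per-group accuracy:** one-vs-rest ("group of interest vs the remaining
  three") in percent; with four roughly equal groups the trivial
  always-rest baseline is ≈75%.
* **ROC-AUC:** one-vs-rest from the SVM decision margins, midrank ties;
  undefined (reported missing) when the evaluation set lacks a class.
* **Permutation test:** p = (1 + #{permuted ≥ observed}) / (1 + n_perm),
  valid (super-uniform under the null) by construction. The statistic is a
  from-scratch pipeline closure — for headline runs a 5-fold CV accuracy of
  screen-then-linear-SVM, refitted per permutation; the full
  selection loop can be substituted at proportionate cost. Defaults:
  1000 permutations for final models, 99 at reduced scale.
* **Leakage guards:** screening, selection and training see training rows
  only; the model records a digest of its training partition and holdout
  evaluation hard-fails on id overlap or digest mismatch. Mutating holdout
  features can change only the evaluation report, bit for bit.

## Reduced problem sizes

The analysis scripts and the acceptance run use one fixed reduced scale
chosen as the package's default desk-scale configuration: 4 groups × 20
subjects, 20 regions, alpha band, 128 Hz, 6 × 10 s epochs, 100 trees,
99 permutations. Null-calibration runs
use an even smaller scale (8 regions, 64 Hz, 3 epochs, power features
only) because calibration of the permutation construction does not depend
on the feature count. The study-scale configuration (90 regions, 4005
edges, groups of 24/27/27/23, seven bands) is fully supported by the same
code paths and is exercised structurally (feature counts, split sizes) in
the tests.

## Known limitations

* The exact univariate test, preprocessing transforms and rRF-FS
  hyperparameters used in comparable clinical analyses vary; the defaults
  here (ANOVA, log10 power, 20% drop fraction, one-SE rule, ≥50% consensus)
  are documented package choices, not claims about any particular study.
* The one-SE parsimony rule interacts with redundant markers: when two
  features carry the same group contrast, folds may keep either, and the
  consensus can legitimately omit a planted feature that is informationally
  redundant. The recovery suite plants markers so that every group pair is
  covered by at least two moderate markers, which is also the regime where
  consensus sets are stable.
* Holdout evaluation at n ≈ 12 has a per-group accuracy quantum of ~8%;
  single-subject flips are visible in the reported percentages.
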