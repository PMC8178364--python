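"""End-to-end orchestration: cohort -> features -> selection -> evaluation.

These helpers glue the stage modules together the way the study design
prescribes: stratified 85/15 holdout first, univariate screening and
CV-SVM-rRF-FS on the training partition only, a final tuned SVM on the
consensus features, PLS-DA verification, a sample-label permutation test,
and a single pass over the holdout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BandDefinition
from .cohort import CohortConfig, EffectSpec, generate_cohort
from .connectivity import aec_features
from .evaluation import (EvaluationReport, SplitSpec, evaluate_holdout,
                         permutation_test, stratified_split)
from .features import FeatureMatrix
from .selection import (CVScheme, ModelBundle, SelectionResult, cv_svm_rrf_fs,
                        partition_hash, plsda_verify, tune_and_train_svm)
from .spectral import regional_power_features
from .univariate import screen_features


def compute_features(cohort, bands: tuple[BandDefinition, ...],
                     feature_type: str = "power",
                     leakage_correction: bool = True) -> FeatureMatrix:
    """Feature matrix of one type over a cohort (``power`` or ``aec``)."""
    if feature_type == "power":
        return regional_power_features(cohort, bands)
    if feature_type == "aec":
        return aec_features(cohort, bands, leakage_correction=leakage_correction)
    raise ValueError(f"unknown feature type {feature_type!r}")


def relabelled(fm: FeatureMatrix, labels: np.ndarray) -> FeatureMatrix:
    """The same features with replacement labels (for permutation closures)."""
    return FeatureMatrix(fm.values.copy(),
                         pd.Series(np.asarray(labels), index=fm.values.index,
                                   name="group"),
                         fm.meta.copy())


def make_screen_svm_statistic(train_fm: FeatureMatrix, alpha_raw: float = 0.05,
                              folds: int = 5, seed: int = 0):
    """A fast from-scratch pipeline statistic for permutation testing.

    Per CV fold: univariate raw-p screen fitted on the fold's training part,
    then a linear SVM on the surviving features, scored on the fold's test
    part. Everything is refitted for whichever labels the closure receives,
    so permuted labels re-run screening and training from scratch.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = train_fm.values
    ids = np.array(train_fm.subject_ids)

    def statistic(labels: np.ndarray) -> float:
        labels = np.asarray(labels)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        correct = 0
        for tr, te in cv.split(ids, labels):
            fm_tr = relabelled(train_fm.subset_subjects(ids[tr]), labels[tr])
            screen = screen_features(fm_tr, alpha_raw=alpha_raw)
            feats = screen.features or train_fm.feature_names
            clf = Pipeline([("sc", StandardScaler()),
                            ("svc", SVC(kernel="linear", C=1.0,
                                        class_weight="balanced"))])
            clf.fit(X.iloc[tr][feats].to_numpy(), labels[tr])
            pred = clf.predict(X.iloc[te][feats].to_numpy())
            correct += int(np.sum(pred == labels[te]))
        return correct / len(ids)

    return statistic


def make_svm_cv_statistic(train_fm: FeatureMatrix, folds: int = 3,
                          seed: int = 0):
    """Mean CV accuracy of a linear SVM on all features (no selection).

    The CV loop is written out directly: at permutation-test scale the
    estimator fits are microseconds and wrapper overhead would dominate.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    X = train_fm.values.to_numpy()

    def statistic(labels: np.ndarray) -> float:
        labels = np.asarray(labels)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in cv.split(X, labels):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
            clf.fit((X[tr] - mu) / sd, labels[tr])
            accs.append(np.mean(clf.predict((X[te] - mu) / sd) == labels[te]))
        return float(np.mean(accs))

    return statistic


def run_selection_and_evaluation(
        fm: FeatureMatrix, split: SplitSpec, scheme: CVScheme | None = None,
        two_step: bool = True, alpha_raw: float = 0.05,
        drop_frac: float = 0.2, min_features: int = 2, n_trees: int = 500,
        inner_folds: int = 3, n_perm: int = 0, perm_seed: int = 0,
        run_plsda: bool = True, plsda_components: int = 3,
        plsda_n_perm: int = 99) -> dict:
    """Full training + evaluation for one feature matrix.

    Returns a dict with keys ``selection`` (:class:`SelectionResult`),
    ``model`` (:class:`ModelBundle`), ``report`` (:class:`EvaluationReport`),
    and optionally ``plsda``. ``n_perm=0`` skips the permutation test.
    """
    scheme = scheme or CVScheme()
    train_fm = fm.subset_subjects(list(split.train_ids))
    holdout_fm = fm.subset_subjects(list(split.holdout_ids))

    selection = cv_svm_rrf_fs(train_fm, scheme=scheme, two_step=two_step,
                              alpha_raw=alpha_raw, drop_frac=drop_frac,
                              min_features=min_features, n_trees=n_trees,
                              inner_folds=inner_folds,
                              holdout_ids=list(split.holdout_ids))

    train_hash = partition_hash(fm, list(split.train_ids))
    if selection.consensus_features:
        model = tune_and_train_svm(
            train_fm.subset_features(selection.consensus_features),
            inner_folds=inner_folds, seed=scheme.seed, train_hash=train_hash)
    else:
        model = tune_and_train_svm(train_fm.subset_features([]),
                                   train_hash=train_hash)

    out: dict = {"selection": selection, "model": model}

    perm_p = None
    if n_perm > 0:
        statistic = make_screen_svm_statistic(train_fm, alpha_raw=alpha_raw,
                                              seed=perm_seed)
        obs, perm_p, _ = permutation_test(statistic,
                                          train_fm.labels.to_numpy(),
                                          n_perm=n_perm, seed=perm_seed)
        out["permutation_observed"] = obs

    if run_plsda and selection.consensus_features:
        out["plsda"] = plsda_verify(
            train_fm.subset_features(selection.consensus_features),
            n_components=plsda_components, n_perm=plsda_n_perm,
            seed=scheme.seed)

    if model.is_model:
        out["report"] = evaluate_holdout(model, holdout_fm, fm, split,
                                         permutation_p=perm_p)
    else:
        out["report"] = None
    return out


def simulate_standard_cohort(seed: int = 0, n_regions: int = 20,
                             n_per_group: dict | None = None,
                             fs: float = 128.0, n_epochs: int = 6,
                             bands: tuple[BandDefinition, ...] | None = None,
                             effects: tuple[EffectSpec, ...] | None = None):
    """A reduced-scale cohort with the standard planted alpha effects.

    Defaults plant three alpha power elevations (magnitude 2.0) and two
    alpha envelope couplings (0.6) distributed over three of the four
    groups, leaving the non-trauma controls as the unaffected baseline.
    """
    from .bands import BAND_MAP

    bands = bands or (BAND_MAP["alpha"],)
    n_per_group = n_per_group or {"PTSD": 20, "TC": 20, "mTBI": 20, "NTC": 20}
    amps = {b.name: 0.7 for b in bands}
    config = CohortConfig(n_per_group=n_per_group, n_regions=n_regions,
                          fs=fs, n_epochs=n_epochs, bands=bands,
                          base_band_amplitudes=amps, seed=seed)
    if effects is None:
        effects = standard_alpha_effects()
    return config, generate_cohort(config, list(effects))


def standard_alpha_effects() -> tuple[EffectSpec, ...]:
    """The default planted ground truth used by recovery analyses.

    Each clinical group carries one regional alpha power elevation; the two
    envelope couplings mark the trauma-related groups, with the second
    shared by mTBI and the trauma-exposed controls so that every pair of
    groups is separated by at least two moderate markers. The non-trauma
    controls are the unaffected baseline.
    """
    return (
        EffectSpec("power", "alpha", 2, ("PTSD",), 2.0),
        EffectSpec("power", "alpha", 5, ("mTBI",), 2.0),
        EffectSpec("power", "alpha", 8, ("TC",), 2.0),
        EffectSpec("edge", "alpha", (10, 11), ("PTSD",), 0.6),
        EffectSpec("edge", "alpha", (13, 14), ("mTBI", "TC"), 0.6),
    )


def planted_feature_names(effects, band: str | None = None) -> list[str]:
    """Conventional feature names for a list of planted effects."""
    names = []
    for e in effects:
        if band is not None and e.band != band:
            continue
        if e.kind == "power":
            names.append(f"pow_{e.band}_{e.regions}")
        else:
            i, j = e.regions
            names.append(f"aec_{e.band}_{i}_{j}")
    return names
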