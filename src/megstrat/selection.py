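"""Nested cross-validated recursive random-forest feature selection with
SVM modelling (CV-SVM-rRF-FS), consensus extraction, and PLS-DA verification.

The engine takes a training feature matrix (the stratified 15% holdout must
already have been removed — an explicit guard enforces this), runs a
stratified 10-fold outer loop, and within each outer fold:

1. optionally reduces features with a raw-p univariate screen fitted on the
   fold's training part (the "two-step" variant);
2. runs recursive random-forest elimination: repeatedly drop the
   lowest-importance fraction of features, tracking inner-CV error at each
   size, and keep the smallest subset within one standard error of the
   minimum;
3. tunes an SVM (linear vs RBF kernel, log-spaced C/gamma grid) on the
   fold's training part and scores the fold's test part per group.

Features selected in at least half the outer folds form the *consensus*
set used to train the final model on all training data. PLS-DA with a
label-permutation test serves as an independent check that the consensus
features generalise beyond the SVM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .univariate import LeakageError, screen_features


def partition_hash(fm: FeatureMatrix, ids: list[str]) -> str:
    """Digest of a subject partition and its feature values (leakage guard)."""
    h = hashlib.sha256()
    for sid in sorted(ids):
        h.update(sid.encode())
    sub = fm.values.loc[sorted(set(ids) & set(fm.subject_ids))]
    h.update(np.ascontiguousarray(sub.to_numpy()).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class CVScheme:
    """Stratified k-fold scheme used for the outer selection loop."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    repeats: int = 1


@dataclass
class SelectionResult:
    """Per-fold selections and accuracies plus the consensus feature set."""

    fold_features: list[list[str]]
    fold_accuracy: list[float]                    # 4-class accuracy per fold
    fold_group_accuracy: pd.DataFrame             # folds x groups, in percent
    consensus_features: list[str]
    consensus_threshold: float
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "fold_features": self.fold_features,
            "fold_accuracy": self.fold_accuracy,
            "fold_group_accuracy": self.fold_group_accuracy.round(10).to_dict(),
            "consensus_features": self.consensus_features,
            "consensus_threshold": self.consensus_threshold,
            "config": self.config,
        }, sort_keys=True)


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed for honest holdout scoring."""

    kind: str                       # "svm" | "plsda" | "none"
    feature_ids: list[str]
    estimator: object | None
    params: dict
    classes: list[str]
    train_hash: str

    @property
    def is_model(self) -> bool:
        return self.estimator is not None

    def _check(self, fm: FeatureMatrix) -> pd.DataFrame:
        if not self.is_model:
            raise RuntimeError("no-model outcome cannot predict")
        missing = set(self.feature_ids) - set(fm.feature_names)
        if missing:
            raise KeyError(f"subjects lack consensus features: {sorted(missing)[:5]}")
        return fm.values[self.feature_ids]

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        X = self._check(fm)
        return self.estimator.predict(X.to_numpy())

    def decision_scores(self, fm: FeatureMatrix) -> pd.DataFrame:
        """Per-class decision scores (one-vs-rest margins or probabilities)."""
        X = self._check(fm).to_numpy()
        est = self.estimator
        if hasattr(est, "decision_function"):
            s = est.decision_function(X)
        else:
            s = est.predict_proba(X)
        if s.ndim == 1:  # binary margin -> two-column form
            s = np.column_stack([-s, s])
        return pd.DataFrame(s, index=fm.subject_ids, columns=self.classes)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "feature_ids": self.feature_ids,
            "params": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                           else str(v)) for k, v in self.params.items()},
            "classes": self.classes,
            "train_hash": self.train_hash,
        }, sort_keys=True)


def rf_rank(X: pd.DataFrame, y: np.ndarray, n_trees: int = 500,
            seed: int = 0) -> list[str]:
    """Features ordered by decreasing mean impurity-decrease importance.

    Ties are broken by the fixed feature-id order (stable sort), so the
    ranking is a deterministic total order.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank features")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                n_jobs=1)
    rf.fit(X.to_numpy(), y)
    imp = rf.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return [X.columns[i] for i in order]


def recursive_rf_select(X: pd.DataFrame, y: np.ndarray,
                        drop_frac: float = 0.2, min_features: int = 2,
                        inner_cv: CVScheme | None = None,
                        n_trees: int = 500, seed: int = 0) -> list[str]:
    """Recursive random-forest elimination with a one-standard-error rule.

    At each step a random forest is fitted on every inner-CV training fold
    of the current subset; the held-out fold errors give the subset's
    inner-CV error, and the fold-averaged impurity-decrease importances
    (more stable than a single full-data fit) rank the features. The
    lowest-ranked ``drop_frac`` of the remaining features is then removed.
    The returned subset is the smallest one whose error is within one SE of
    the minimum error.
    """
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    if min_features > X.shape[1]:
        raise ValueError("min_features exceeds the number of features")
    inner_cv = inner_cv or CVScheme(n_folds=3, seed=seed)
    y = np.asarray(y)

    cv = StratifiedKFold(n_splits=inner_cv.n_folds, shuffle=True,
                         random_state=inner_cv.seed)
    current = list(X.columns)
    col_order = {c: k for k, c in enumerate(X.columns)}
    history: list[tuple[list[str], float, float]] = []  # (subset, err, se)
    step = 0
    while True:
        Xc = X[current].to_numpy()
        errs, importances = [], np.zeros(len(current))
        for k, (tr, te) in enumerate(cv.split(Xc, y)):
            rf = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + step + 7919 * k,
                                        n_jobs=1)
            rf.fit(Xc[tr], y[tr])
            errs.append(1.0 - rf.score(Xc[te], y[te]))
            importances += rf.feature_importances_
        errs = np.asarray(errs)
        history.append((list(current),
                        float(errs.mean()),
                        float(errs.std(ddof=1) / np.sqrt(len(errs)))))
        if len(current) <= min_features:
            break
        order = np.argsort(-importances, kind="stable")
        n_drop = max(1, int(np.floor(drop_frac * len(current))))
        n_keep = max(min_features, len(current) - n_drop)
        current = sorted((current[i] for i in order[:n_keep]),
                         key=col_order.__getitem__)
        step += 1

    errs = np.array([e for _, e, _ in history])
    best = int(np.argmin(errs))
    threshold = errs[best] + history[best][2]
    # smallest subset (last recorded) within one SE of the minimum
    within = [k for k in range(len(history)) if errs[k] <= threshold]
    return history[max(within)][0]


def _svm_grid(kernels=("linear", "rbf"),
              C_grid=(0.1, 1.0, 10.0, 100.0),
              gamma_grid=("scale", 0.01, 0.1, 1.0)) -> list[dict]:
    grid: list[dict] = []
    if "linear" in kernels:
        grid.append({"svc__kernel": ["linear"], "svc__C": list(C_grid)})
    if "rbf" in kernels:
        grid.append({"svc__kernel": ["rbf"], "svc__C": list(C_grid),
                     "svc__gamma": list(gamma_grid)})
    return grid


def tune_and_train_svm(fm: FeatureMatrix, kernels=("linear", "rbf"),
                       inner_folds: int = 3, seed: int = 0,
                       train_hash: str | None = None) -> ModelBundle:
    """Kernel/hyperparameter selection by inner CV, then fit on all rows.

    The parameter grid is ordered linear-first with ascending C, and
    GridSearchCV keeps the first best configuration, so ties resolve toward
    the more parsimonious model. Class weights are inverse to group size
    (the four groups are mildly unbalanced).
    """
    if fm.n_features == 0:
        return ModelBundle(kind="none", feature_ids=[], estimator=None,
                           params={"reason": "empty consensus feature set"},
                           classes=sorted(pd.unique(fm.labels)),
                           train_hash=train_hash or "")
    y = fm.labels.to_numpy()
    pipe = Pipeline([
        ("scaler", StandardScaler()),
        ("svc", SVC(class_weight="balanced", decision_function_shape="ovr")),
    ])
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, _svm_grid(kernels), cv=cv, scoring="accuracy",
                      n_jobs=1, refit=True)
    gs.fit(fm.values.to_numpy(), y)
    params = {k.replace("svc__", ""): v for k, v in gs.best_params_.items()}
    params["inner_cv_accuracy"] = float(gs.best_score_)
    return ModelBundle(kind="svm", feature_ids=fm.feature_names,
                       estimator=gs.best_estimator_, params=params,
                       classes=[str(c) for c in gs.best_estimator_.classes_],
                       train_hash=train_hash or "")


def cv_svm_rrf_fs(train_fm: FeatureMatrix, scheme: CVScheme | None = None,
                  two_step: bool = False, alpha_raw: float = 0.05,
                  drop_frac: float = 0.2, min_features: int = 2,
                  n_trees: int = 500, consensus_frac: float = 0.5,
                  inner_folds: int = 3,
                  holdout_ids: list[str] | None = None) -> SelectionResult:
    """The outer selection loop over a training feature matrix.

    ``holdout_ids`` is the excluded evaluation partition; any overlap with
    the input raises a :class:`~megstrat.univariate.LeakageError`.
    """
    from .evaluation import per_group_accuracy  # local import avoids a cycle

    scheme = scheme or CVScheme()
    holdout_ids = list(holdout_ids or [])
    overlap = set(holdout_ids) & set(train_fm.subject_ids)
    if overlap:
        raise LeakageError(f"holdout subjects inside the selection loop: "
                           f"{sorted(overlap)[:5]}")

    y = train_fm.labels.to_numpy()
    groups = sorted(pd.unique(train_fm.labels))
    counts = train_fm.labels.value_counts()
    if scheme.stratified and counts.min() < scheme.n_folds:
        # every fold still holds >=1 test subject of the largest groups, but
        # sklearn errors if any class has fewer members than folds
        if counts.min() < 2:
            raise ValueError("stratified CV needs >= 2 subjects per group")

    outer = StratifiedKFold(n_splits=scheme.n_folds, shuffle=True,
                            random_state=scheme.seed)
    ids = np.array(train_fm.subject_ids)

    fold_features: list[list[str]] = []
    fold_accuracy: list[float] = []
    fold_group_rows: list[dict] = []

    for fold, (tr, te) in enumerate(outer.split(ids, y)):
        tr_fm = train_fm.subset_subjects(ids[tr])
        te_fm = train_fm.subset_subjects(ids[te])

        pool = tr_fm
        if two_step:
            screen = screen_features(tr_fm, alpha_raw=alpha_raw,
                                     holdout_ids=holdout_ids)
            if screen.features:
                pool = tr_fm.subset_features(screen.features)
            else:
                pool = tr_fm.subset_features([])

        if pool.n_features == 0:
            selected: list[str] = []
        else:
            selected = recursive_rf_select(
                pool.values, pool.labels.to_numpy(), drop_frac=drop_frac,
                min_features=min(min_features, pool.n_features),
                inner_cv=CVScheme(n_folds=inner_folds, seed=scheme.seed + fold),
                n_trees=n_trees, seed=scheme.seed * 1000 + fold)
        fold_features.append(sorted(selected))

        if selected:
            bundle = tune_and_train_svm(tr_fm.subset_features(selected),
                                        inner_folds=inner_folds,
                                        seed=scheme.seed + fold)
            pred = bundle.predict(te_fm.subset_features(selected))
        else:
            majority = tr_fm.labels.mode().iloc[0]
            pred = np.full(te_fm.n_subjects, majority, dtype=object)
        truth = te_fm.labels.to_numpy()
        fold_accuracy.append(float(np.mean(pred == truth)))
        fold_group_rows.append({g: per_group_accuracy(pred, truth, g)
                                for g in groups})

    n_folds = len(fold_features)
    votes: dict[str, int] = {}
    for feats in fold_features:
        for f in feats:
            votes[f] = votes.get(f, 0) + 1
    consensus = sorted(f for f, v in votes.items()
                       if v >= consensus_frac * n_folds)

    return SelectionResult(
        fold_features=fold_features,
        fold_accuracy=fold_accuracy,
        fold_group_accuracy=pd.DataFrame(fold_group_rows),
        consensus_features=consensus,
        consensus_threshold=consensus_frac,
        config={"n_folds": scheme.n_folds, "seed": scheme.seed,
                "two_step": two_step, "alpha_raw": alpha_raw,
                "drop_frac": drop_frac, "n_trees": n_trees,
                "consensus_frac": consensus_frac,
                "train_hash": partition_hash(train_fm, train_fm.subject_ids)})


def plsda_verify(fm: FeatureMatrix, n_components: int = 3,
                 n_perm: int = 199, seed: int = 0,
                 cv_folds: int = 5) -> dict:
    """PLS-DA check that consensus features generalise beyond the SVM.

    Fits partial least squares on a one-hot response, scores CV accuracy by
    argmax of the predicted responses, and permutes sample labels to obtain
    a permutation p-value. A p >= 0.05 raises the ``svm_only`` flag: the
    feature set discriminates under the SVM but not under this independent
    linear classifier.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = fm.values.to_numpy()
    y = fm.labels.to_numpy()
    classes = np.array(sorted(pd.unique(fm.labels)))
    ncomp = min(n_components, X.shape[1], X.shape[0] - 2)

    def cv_accuracy(labels: np.ndarray, split_seed: int) -> float:
        Y = (labels[:, None] == classes[None, :]).astype(float)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=split_seed)
        correct = 0
        for tr, te in cv.split(X, labels):
            pls = PLSRegression(n_components=ncomp, scale=True)
            pls.fit(X[tr], Y[tr])
            pred = classes[np.argmax(pls.predict(X[te]), axis=1)]
            correct += int(np.sum(pred == labels[te]))
        return correct / len(labels)

    observed = cv_accuracy(y, split_seed=seed)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if cv_accuracy(perm, split_seed=seed) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return {"cv_accuracy": observed, "p_value": p, "n_perm": n_perm,
            "n_components": ncomp, "svm_only": bool(p >= 0.05)}
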