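"""Holdout management, per-group one-vs-rest metrics, permutation testing.

The study design holds out a stratified 15% of subjects before any
screening, selection or training; the final model sees them exactly once.
Per-group performance is reported as one-vs-rest accuracy (the binarised
decision "group of interest vs the remaining three") in percent, plus a
one-vs-rest ROC-AUC per group and a sample-label permutation p-value for
the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .features import FeatureMatrix
from .univariate import LeakageError


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/holdout partition of subject ids."""

    train_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.holdout_ids):
            raise ValueError("train and holdout ids overlap")


def stratified_split(labels: pd.Series, fraction: float = 0.85,
                     seed: int = 0) -> SplitSpec:
    """Stratified train/holdout split of subjects.

    Per-group holdout counts use largest-remainder rounding of
    ``(1 - fraction) * n_group`` with a floor of one holdout subject per
    group, so proportions are within one subject of the target.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    counts = labels.value_counts()
    if counts.min() < 2:
        small = list(counts.index[counts < 2])
        raise ValueError(f"groups with < 2 subjects cannot be split: {small}")

    groups = sorted(counts.index)
    exact = {g: (1 - fraction) * counts[g] for g in groups}
    n_hold = {g: max(1, int(np.floor(exact[g]))) for g in groups}
    total_target = int(round((1 - fraction) * counts.sum()))
    remainders = sorted(groups, key=lambda g: exact[g] - np.floor(exact[g]),
                        reverse=True)
    k = 0
    while sum(n_hold.values()) < total_target and k < len(remainders):
        g = remainders[k]
        if n_hold[g] < counts[g] - 1:
            n_hold[g] += 1
        k += 1

    rng = np.random.default_rng(seed)
    holdout: list[str] = []
    for g in groups:
        ids = np.array(labels.index[labels == g])
        holdout.extend(rng.choice(ids, size=n_hold[g], replace=False))
    train = [s for s in labels.index if s not in set(holdout)]
    return SplitSpec(tuple(train), tuple(holdout), fraction, seed)


def per_group_accuracy(predictions: Sequence, labels: Sequence,
                       group: str) -> float:
    """One-vs-rest accuracy for ``group``, in percent.

    Both prediction and truth are binarised to "group vs rest"; the score
    is the fraction of subjects on the correct side, times 100.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    if group not in set(labels) | set(predictions):
        raise ValueError(f"unknown group {group!r}")
    return float(100.0 * np.mean((predictions == group) == (labels == group)))


def ovr_auc(scores: pd.DataFrame, labels: Sequence, group: str) -> float | None:
    """One-vs-rest ROC-AUC for ``group`` from per-class decision scores.

    Ties in the scores are handled by midranks (Mann–Whitney equivalence).
    Returns None when the evaluation set lacks either the group or the
    rest — the AUC is undefined there and reported as missing.
    """
    labels = np.asarray(labels)
    if group not in scores.columns:
        raise ValueError(f"no scores for group {group!r}")
    pos = labels == group
    if pos.all() or not pos.any():
        return None
    return float(roc_auc_score(pos.astype(int), scores[group].to_numpy()))


def permutation_test(statistic: Callable[[np.ndarray], float],
                     labels: np.ndarray, n_perm: int = 1000,
                     seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Sample-label permutation test of a pipeline statistic.

    ``statistic`` must re-run the full pipeline (screening, selection,
    training, CV scoring) from scratch for the labels it is given — nothing
    selected under the true labels may be reused. Returns
    ``(observed, p, permuted_scores)`` with the add-one estimate
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``, which is valid
    (super-uniform under the null) by construction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = float(statistic(labels))
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        permuted[b] = statistic(rng.permutation(labels))
    p = (1 + int(np.sum(permuted >= observed))) / (1 + n_perm)
    return observed, float(p), permuted


@dataclass
class EvaluationReport:
    """Final holdout evaluation with full provenance."""

    group_accuracy: dict[str, float]              # percent
    group_auc: dict[str, float | None]
    confusion: pd.DataFrame                       # rows: true, cols: predicted
    accuracy: float                               # 4-class, fraction
    permutation_p: float | None
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "group_accuracy": self.group_accuracy,
            "group_auc": self.group_auc,
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "permutation_p": self.permutation_p,
            "config": self.config,
        }, sort_keys=True)


def evaluate_holdout(model, holdout_fm: FeatureMatrix, full_fm: FeatureMatrix,
                     split: SplitSpec, permutation_p: float | None = None,
                     extra_config: dict | None = None) -> EvaluationReport:
    """Score a fitted model bundle on the untouched holdout subjects.

    Hard-fails if the holdout overlaps the model's training partition or if
    the recorded training-partition digest does not match the training rows
    of ``full_fm`` (tamper evidence).
    """
    from .selection import partition_hash

    overlap = set(holdout_fm.subject_ids) & set(split.train_ids)
    if overlap:
        raise LeakageError(f"holdout overlaps training ids: {sorted(overlap)[:5]}")
    expected = partition_hash(full_fm, list(split.train_ids))
    if model.train_hash and model.train_hash != expected:
        raise LeakageError("training partition digest mismatch: the model was "
                           "not fitted on the declared training partition")

    truth = holdout_fm.labels.to_numpy()
    groups = sorted(set(full_fm.labels))
    pred = model.predict(holdout_fm)
    scores = model.decision_scores(holdout_fm)

    acc = {g: per_group_accuracy(pred, truth, g) for g in groups}
    auc = {g: ovr_auc(scores, truth, g) for g in groups}
    cm = confusion_matrix(truth, pred, labels=groups)
    confusion = pd.DataFrame(cm, index=groups, columns=groups)

    cfg = {"split_seed": split.seed, "fraction": split.fraction,
           "n_holdout": len(holdout_fm.subject_ids),
           "train_hash": model.train_hash}
    cfg.update(extra_config or {})
    return EvaluationReport(group_accuracy=acc, group_auc=auc,
                            confusion=confusion,
                            accuracy=float(np.mean(pred == truth)),
                            permutation_p=permutation_p, config=cfg)
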