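"""Univariate group screening, FDR control, and exploratory views.

Used two ways: (i) standalone on the complete data with Benjamini–Hochberg
FDR thresholding, to ask whether simple per-feature tests already separate
the four groups; and (ii) as the first step of the two-step pipeline, where
a raw-p threshold fitted on *training subjects only* reduces the feature
space before recursive selection (holdout subjects must never enter this
fit — an explicit leakage check enforces it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix


class LeakageError(RuntimeError):
    """A training-only operation saw holdout subjects."""


@dataclass
class UnivariateResult:
    """Per-feature test results with raw and FDR-adjusted p-values."""

    table: pd.DataFrame  # index: feature; columns statistic, p_raw, p_fdr

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p_fdr"] < alpha])


@dataclass
class ScreenSet:
    """Features surviving the raw-p training-only reduction."""

    features: list[str]
    alpha: float
    train_ids: list[str] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        import hashlib
        import json
        partition = hashlib.sha256(
            ",".join(sorted(self.train_ids)).encode()).hexdigest()[:16]
        return json.dumps({"features": self.features, "alpha": self.alpha,
                           "partition_hash": partition,
                           "n_excluded": len(self.excluded_ids)},
                          sort_keys=True)


def groupwise_test(values: np.ndarray, labels: np.ndarray,
                   method: str = "anova") -> tuple[float, float]:
    """One-way four-group location test for a single feature.

    ``method='anova'`` (one-way F) or ``'kruskal'`` (Kruskal–Wallis).
    A zero-variance feature is degenerate and returns (0, 1) with a warning.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, float)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs >= 2 subjects")
    if np.ptp(values) == 0:
        warnings.warn("constant feature: test degenerate, p set to 1")
        return 0.0, 1.0
    if method == "anova":
        stat, p = stats.f_oneway(*groups)
    elif method == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(p):  # e.g. zero within-group variance
        return float(stat) if np.isfinite(stat) else 0.0, 1.0
    return float(stat), float(p)


def fdr_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_raw, float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and non-NaN")
    return multipletests(p, method="fdr_bh")[1]


def univariate_table(fm: FeatureMatrix, method: str = "anova") -> UnivariateResult:
    """Test every feature for a four-group difference; BH-adjust across features."""
    X = fm.values.to_numpy()
    y = fm.labels.to_numpy()
    stats_p = [groupwise_test(X[:, k], y, method=method)
               for k in range(X.shape[1])]
    stat = np.array([s for s, _ in stats_p])
    p_raw = np.array([p for _, p in stats_p])
    table = pd.DataFrame({"statistic": stat, "p_raw": p_raw,
                          "p_fdr": fdr_adjust(p_raw)},
                         index=fm.feature_names)
    return UnivariateResult(table)


def screen_features(train_fm: FeatureMatrix, alpha_raw: float = 0.05,
                    holdout_ids: list[str] | None = None,
                    method: str = "anova") -> ScreenSet:
    """Raw-p feature reduction fitted on training subjects only.

    ``holdout_ids`` documents the excluded partition; if any of them appear
    in ``train_fm`` a :class:`LeakageError` is raised.
    """
    holdout_ids = list(holdout_ids or [])
    overlap = set(holdout_ids) & set(train_fm.subject_ids)
    if overlap:
        raise LeakageError(f"holdout subjects present in screening input: "
                           f"{sorted(overlap)[:5]}")
    if alpha_raw <= 0:
        return ScreenSet([], alpha_raw, train_fm.subject_ids, holdout_ids)
    res = univariate_table(train_fm, method=method)
    keep = list(res.table.index[res.table["p_raw"] < alpha_raw])
    return ScreenSet(keep, alpha_raw, train_fm.subject_ids, holdout_ids)


@dataclass
class ZScorer:
    """Per-feature standardisation fitted on a training partition only."""

    means: pd.Series
    sds: pd.Series
    fit_ids: list[str]
    zero_sd_features: list[str]

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        z = (values - self.means) / self.sds.replace(0.0, 1.0)
        if self.zero_sd_features:
            z[self.zero_sd_features] = 0.0
        return z


def zscore_fit_transform(fm: FeatureMatrix, fit_ids: list[str]
                         ) -> tuple[pd.DataFrame, ZScorer]:
    """Standardise all rows using mean/SD estimated from ``fit_ids`` only."""
    missing = set(fit_ids) - set(fm.subject_ids)
    if missing:
        raise KeyError(f"fit ids not in matrix: {sorted(missing)[:5]}")
    sub = fm.values.loc[list(fit_ids)]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=1)
    zero = list(sds.index[sds == 0])
    scaler = ZScorer(means, sds, list(fit_ids), zero)
    return scaler.transform(fm.values), scaler


def hierarchical_cluster(z: pd.DataFrame, labels: pd.Series | None = None,
                         n_clusters: int = 4) -> dict:
    """Agglomerative clustering on both axes of a standardised matrix.

    Subjects: Euclidean distance, Ward linkage. Features: correlation
    distance, average linkage. Returns linkages, top-level subject cluster
    assignments, and (if true labels are given) the adjusted Rand index
    between clusters and groups.
    """
    X = z.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least two subjects to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries")
    subj_link = hierarchy.linkage(X, method="ward", metric="euclidean")
    if X.shape[1] >= 2:
        # guard correlation distance against constant feature columns
        Xf = X.T + 1e-12 * np.random.default_rng(0).standard_normal(X.T.shape)
        feat_link = hierarchy.linkage(pdist(Xf, metric="correlation"),
                                      method="average")
    else:
        feat_link = None
    clusters = hierarchy.fcluster(subj_link, t=n_clusters, criterion="maxclust")
    out = {"subject_linkage": subj_link, "feature_linkage": feat_link,
           "subject_clusters": clusters}
    if labels is not None:
        out["adjusted_rand"] = float(adjusted_rand_score(labels.to_numpy(),
                                                         clusters))
    return out


def pca_scores(z: pd.DataFrame, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """First ``k`` principal-component scores and explained-variance fractions."""
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, min(z.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=z.index, columns=cols),
            pca.explained_variance_ratio_)
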