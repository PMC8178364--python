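"""CV-SVM-rRF-FS engine: ranking, recursive elimination, tuning, PLS-DA."""

import numpy as np
import pytest

from megstrat.selection import (CVScheme, cv_svm_rrf_fs, plsda_verify,
                                recursive_rf_select, rf_rank,
                                tune_and_train_svm)
from megstrat.univariate import LeakageError


class TestRFRank:
    def test_label_determined_feature_ranked_first(self, fm_factory):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b"], 20)
        hits = 0
        for s in range(10):
            X = rng.standard_normal((40, 30))
            X[:, 7] = (labels == "a") * 2.0 + 0.01 * rng.standard_normal(40)
            fm = fm_factory(X, labels)
            ranked = rf_rank(fm.values, labels, n_trees=100, seed=s)
            hits += ranked[0] == "pow_alpha_7"
        assert hits >= 9

    def test_all_noise_rankings_unstable_across_reseeds(self, fm_factory):
        rng = np.random.default_rng(1)
        labels = np.repeat(["a", "b"], 15)
        X = rng.standard_normal((30, 40))
        fm = fm_factory(X, labels)
        r1 = rf_rank(fm.values, labels, n_trees=50, seed=1)
        r2 = rf_rank(fm.values, labels, n_trees=50, seed=2)
        pos1 = {f: i for i, f in enumerate(r1)}
        pos2 = {f: i for i, f in enumerate(r2)}
        rho = np.corrcoef([pos1[f] for f in r1], [pos2[f] for f in r1])[0, 1]
        assert abs(rho) < 0.5

    def test_single_class_rejected(self, fm_factory):
        fm = fm_factory(np.random.default_rng(2).standard_normal((10, 3)),
                        ["a"] * 10)
        with pytest.raises(ValueError):
            rf_rank(fm.values, fm.labels.to_numpy())


class TestRecursiveSelect:
    def test_informative_features_recovered_from_noise(self, fm_factory):
        # moderate markers: no tiny subset separates perfectly, so the
        # one-SE rule keeps the informative set while shedding the noise
        rng = np.random.default_rng(3)
        labels = np.repeat(["a", "b", "c", "d"], 15)
        X = rng.standard_normal((60, 105))
        informative = [f"pow_alpha_{k}" for k in range(5)]
        X[labels == "a", 0] += 2
        X[labels == "b", 1] += 2
        X[labels == "c", 2] += 2
        X[labels == "d", 3] += 2
        X[np.isin(labels, ["a", "c"]), 4] += 2
        fm = fm_factory(X, labels)
        sel = recursive_rf_select(fm.values, labels, n_trees=100, seed=0)
        assert len(set(sel) & set(informative)) >= 4
        assert len(sel) <= 30

    def test_all_noise_selection_is_not_predictive(self, fm_factory):
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC
        rng = np.random.default_rng(4)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        fm = fm_factory(rng.standard_normal((40, 50)), labels)
        sel = recursive_rf_select(fm.values, labels, n_trees=50, seed=0)
        acc = cross_val_score(SVC(), fm.values[sel].to_numpy(), labels,
                              cv=4).mean()
        assert acc < 0.55  # chance is 0.25; generous head-room for overfit

    def test_parameter_validation(self, fm_factory):
        fm = fm_factory(np.zeros((8, 4)), ["a", "b"] * 4)
        with pytest.raises(ValueError):
            recursive_rf_select(fm.values, fm.labels.to_numpy(), drop_frac=1.5)
        with pytest.raises(ValueError):
            recursive_rf_select(fm.values, fm.labels.to_numpy(),
                                min_features=10)


class TestSVMTuning:
    def test_linearly_separable_selects_linear_kernel(self, fm_factory):
        rng = np.random.default_rng(5)
        labels = np.repeat(["a", "b"], 20)
        X = rng.standard_normal((40, 2))
        X[labels == "a", 0] += 8.0
        bundle = tune_and_train_svm(fm_factory(X, labels), seed=0)
        assert bundle.params["kernel"] == "linear"
        assert bundle.params["inner_cv_accuracy"] == 1.0

    def test_xor_structure_prefers_rbf(self, fm_factory):
        rng = np.random.default_rng(6)
        n = 200
        X = rng.uniform(-1, 1, (n, 2))
        labels = np.where(X[:, 0] * X[:, 1] > 0, "a", "b")
        bundle = tune_and_train_svm(fm_factory(X, labels), seed=0)
        assert bundle.params["kernel"] == "rbf"
        assert bundle.params["inner_cv_accuracy"] > 0.9

    def test_empty_feature_set_yields_no_model_outcome(self, fm_factory):
        fm = fm_factory(np.zeros((8, 0)), ["a", "b"] * 4)
        bundle = tune_and_train_svm(fm)
        assert bundle.kind == "none" and not bundle.is_model
        with pytest.raises(RuntimeError):
            bundle.predict(fm)

    def test_prediction_requires_declared_features(self, fm_factory):
        rng = np.random.default_rng(7)
        fm = fm_factory(rng.standard_normal((20, 3)), ["a", "b"] * 10)
        bundle = tune_and_train_svm(fm, seed=0)
        with pytest.raises(KeyError):
            bundle.predict(fm.subset_features(fm.feature_names[:2]))


@pytest.fixture(scope="module")
def informative_fm():
    from tests.conftest import make_feature_matrix
    rng = np.random.default_rng(8)
    labels = np.repeat(["a", "b", "c", "d"], 15)
    X = rng.standard_normal((60, 25))
    X[labels == "a", 0] += 3
    X[labels == "b", 1] += 3
    X[labels == "c", 2] += 3
    return make_feature_matrix(X, labels)


class TestCVSVMRRFFS:

    def test_planted_features_reach_consensus(self, informative_fm):
        res = cv_svm_rrf_fs(informative_fm, CVScheme(n_folds=5, seed=0),
                            n_trees=100)
        assert {"pow_alpha_0", "pow_alpha_1",
                "pow_alpha_2"} <= set(res.consensus_features)
        assert np.mean(res.fold_accuracy) > 0.7
        assert ((res.fold_group_accuracy >= 0) &
                (res.fold_group_accuracy <= 100)).all().all()

    def test_same_seed_reproduces_bitwise(self, informative_fm):
        r1 = cv_svm_rrf_fs(informative_fm, CVScheme(n_folds=5, seed=3),
                           n_trees=50)
        r2 = cv_svm_rrf_fs(informative_fm, CVScheme(n_folds=5, seed=3),
                           n_trees=50)
        assert r1.to_json() == r2.to_json()

    def test_shuffled_labels_fall_to_chance(self, informative_fm, fm_factory):
        rng = np.random.default_rng(9)
        shuffled = fm_factory(informative_fm.values.to_numpy(),
                              rng.permutation(informative_fm.labels.to_numpy()))
        res = cv_svm_rrf_fs(shuffled, CVScheme(n_folds=5, seed=0), n_trees=50)
        assert np.mean(res.fold_accuracy) < 0.45  # chance = 0.25

    def test_holdout_overlap_is_a_hard_leakage_error(self, informative_fm):
        with pytest.raises(LeakageError):
            cv_svm_rrf_fs(informative_fm, CVScheme(n_folds=5, seed=0),
                          holdout_ids=[informative_fm.subject_ids[0]])


class TestPLSDA:
    def test_strong_structure_is_significant(self, fm_factory,
                                             gaussian_groups):
        X, labels = gaussian_groups
        out = plsda_verify(fm_factory(X[:, :6], labels), n_perm=99, seed=0)
        assert out["p_value"] < 0.05 and not out["svm_only"]
        again = plsda_verify(fm_factory(X[:, :6], labels), n_perm=99, seed=0)
        assert again["p_value"] == out["p_value"]

    def test_pure_noise_flags_svm_only(self, fm_factory):
        rng = np.random.default_rng(10)
        fm = fm_factory(rng.standard_normal((40, 6)),
                        np.repeat(["a", "b", "c", "d"], 10))
        out = plsda_verify(fm, n_perm=49, seed=1)
        assert out["p_value"] > 0.05 and out["svm_only"]

    def test_parameter_validation(self, fm_factory, gaussian_groups):
        X, labels = gaussian_groups
        with pytest.raises(ValueError):
            plsda_verify(fm_factory(X, labels), n_components=0)
        with pytest.raises(ValueError):
            plsda_verify(fm_factory(X, labels), n_perm=0)
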