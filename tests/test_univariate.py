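"""Screening stage: group tests, BH-FDR against brute force, leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megstrat.univariate import (LeakageError, fdr_adjust, groupwise_test,
                                 hierarchical_cluster, pca_scores,
                                 screen_features, univariate_table,
                                 zscore_fit_transform)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Direct step-up definition: p_(i) * m / i, cumulative-min from the top."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestGroupwiseTest:
    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b", "c", "d"], 20)
        x = rng.standard_normal(80)
        x[labels == "b"] += 5.0
        stat, p = groupwise_test(x, labels)
        assert p < 1e-6
        stat_k, p_k = groupwise_test(x, labels, method="kruskal")
        assert p_k < 1e-6

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        ps = [groupwise_test(rng.standard_normal(40), labels)[1]
              for _ in range(300)]
        assert 0.2 < np.mean(ps) < 0.8
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_constant_feature_degenerates_to_p_one(self):
        labels = np.repeat(["a", "b"], 5)
        with pytest.warns(UserWarning):
            stat, p = groupwise_test(np.ones(10), labels)
        assert p == 1.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            groupwise_test(np.arange(5.0), np.array(["a"] * 4 + ["b"]))


class TestFDR:
    def test_hand_computed_step_up_case(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m)
            assert fdr_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_monotone_in_rank_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.lists(st.floats(min_value=0.0, max_value=1.0),
                      min_size=1, max_size=50))
    def test_step_up_property_holds_for_arbitrary_p_vectors(self, p):
        p = np.asarray(p)
        adj = fdr_adjust(p)
        assert adj == pytest.approx(brute_force_bh(p))
        assert np.all((0 <= adj) & (adj <= 1))


class TestScreening:
    def test_null_screen_retains_about_alpha_fraction(self, fm_factory):
        rng = np.random.default_rng(4)
        m = 400
        fm = fm_factory(rng.standard_normal((40, m)),
                        np.repeat(["a", "b", "c", "d"], 10))
        kept = screen_features(fm, alpha_raw=0.05).features
        # Binomial(400, 0.05): mean 20, sd ~4.4
        assert 4 <= len(kept) <= 40

    def test_planted_effect_always_retained(self, fm_factory, gaussian_groups):
        X, labels = gaussian_groups
        fm = fm_factory(X, labels)
        kept = screen_features(fm, alpha_raw=0.05).features
        assert "pow_alpha_0" in kept and "pow_alpha_1" in kept

    def test_alpha_zero_gives_empty_set(self, fm_factory, gaussian_groups):
        X, labels = gaussian_groups
        assert screen_features(fm_factory(X, labels), alpha_raw=0.0).features == []

    def test_holdout_subject_in_input_is_a_leakage_error(self, fm_factory,
                                                         gaussian_groups):
        X, labels = gaussian_groups
        fm = fm_factory(X, labels)
        with pytest.raises(LeakageError):
            screen_features(fm, holdout_ids=[fm.subject_ids[0]])


class TestZScore:
    def test_fit_rows_standardised_holdout_uses_training_stats(self, fm_factory):
        rng = np.random.default_rng(5)
        fm = fm_factory(rng.standard_normal((20, 6)) * 3 + 1,
                        ["a", "b", "c", "d"] * 5)
        fit_ids = fm.subject_ids[:16]
        z, scaler = zscore_fit_transform(fm, fit_ids)
        assert z.loc[fit_ids].mean(axis=0).to_numpy() == pytest.approx(
            np.zeros(6), abs=1e-10)
        assert z.loc[fit_ids].std(axis=0, ddof=1).to_numpy() == pytest.approx(
            np.ones(6))
        # holdout rows transformed with training statistics, not their own
        hold = fm.subject_ids[16:]
        own = (fm.values.loc[hold] - fm.values.loc[hold].mean()) / \
            fm.values.loc[hold].std(ddof=1)
        assert not np.allclose(z.loc[hold].to_numpy(), own.to_numpy())

    def test_zero_sd_feature_maps_to_zero(self, fm_factory):
        X = np.random.default_rng(6).standard_normal((8, 2))
        X[:, 1] = 2.5
        fm = fm_factory(X, ["a", "b"] * 4)
        z, scaler = zscore_fit_transform(fm, fm.subject_ids)
        assert scaler.zero_sd_features == ["pow_alpha_1"]
        assert np.all(z.iloc[:, 1] == 0.0)


class TestClusterAndPCA:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 5))
        X[15:] += 12.0
        z = pd.DataFrame(X)
        labels = pd.Series(["a"] * 15 + ["b"] * 15)
        out = hierarchical_cluster(z, labels, n_clusters=2)
        assert out["adjusted_rand"] == pytest.approx(1.0)

    def test_label_free_noise_has_low_rand(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.standard_normal((40, 5)))
        labels = pd.Series(rng.permutation(["a", "b", "c", "d"] * 10))
        out = hierarchical_cluster(z, labels, n_clusters=4)
        assert abs(out["adjusted_rand"]) < 0.2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame(np.zeros((1, 3))))

    def test_pca_fractions_non_increasing_and_rank_one(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((20, 1)) @ rng.standard_normal((1, 6))
        scores, frac = pca_scores(pd.DataFrame(base), k=3)
        assert frac[0] == pytest.approx(1.0)
        scores2, frac2 = pca_scores(
            pd.DataFrame(rng.standard_normal((20, 6))), k=4)
        assert np.all(np.diff(frac2) <= 1e-12)
        with pytest.raises(ValueError):
            pca_scores(pd.DataFrame(base), k=0)


def test_univariate_table_planted_feature_tops_ranking(fm_factory,
                                                       gaussian_groups):
    X, labels = gaussian_groups
    res = univariate_table(fm_factory(X, labels))
    top2 = set(res.table.nsmallest(2, "p_raw").index)
    assert top2 == {"pow_alpha_0", "pow_alpha_1"}
    assert res.significant(0.05) and \
        set(res.significant(0.05)) <= set(res.table.index)
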