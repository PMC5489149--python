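"""Scorer-level tests: profile methods, AUC, maxSSS threshold, SSB matching.

Brute-force oracles are implemented inline and kept independent of the
library code paths they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdm2abund.sdm import (
    auc,
    fit_score_glm,
    fit_score_ml,
    max_sss_threshold,
    score_bioclim,
    score_domain,
    score_mahalanobis,
    ssb_adjust,
)


# ---------------------------------------------------------------- oracles

def auc_bruteforce(p, a):
    wins = 0.0
    for x in p:
        for y in a:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(p) * len(a))


def maxsss_dense_grid(p, a):
    pooled = np.concatenate([p, a])
    grid = np.linspace(pooled.min() - 0.01, pooled.max() + 0.01, 4001)
    best_val, best_t = -1.0, None
    for t in grid:
        s = np.mean(p >= t) + np.mean(a < t)
        if s > best_val + 1e-12:
            best_val, best_t = s, t
    return best_val


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_enumeration(self):
        assert auc([0.9, 0.4], [0.6, 0.1]) == 0.75

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            auc([], [0.1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    def test_property_complement_symmetry(self, p, a):
        """Swapping the groups reflects the statistic: AUC(p,a) = 1 - AUC(a,p)."""
        p = np.asarray(p) / 8.0
        a = np.asarray(a) / 8.0
        assert auc(p, a) == pytest.approx(1.0 - auc(a, p))

    def test_matches_bruteforce_on_fuzzed_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_p = rng.integers(1, 8)
            n_a = rng.integers(1, 8)
            # quantized scores so ties actually occur
            p = rng.integers(0, 5, n_p) / 4.0
            a = rng.integers(0, 5, n_a) / 4.0
            assert auc(p, a) == pytest.approx(auc_bruteforce(p, a))


class TestMaxSSS:
    def test_midpoint_between_groups(self):
        assert max_sss_threshold([0.8, 0.9], [0.1, 0.2]) == pytest.approx(0.5)

    def test_single_tied_value(self):
        # sens 1, spec 0 at the only candidate
        assert max_sss_threshold([0.3], [0.3]) == pytest.approx(0.3)

    def test_identical_distributions_lowest_candidate(self):
        p = np.array([0.2, 0.5, 0.8])
        t = max_sss_threshold(p, p)
        s = np.mean(p >= t) + np.mean(p < t)
        assert s <= 1.0 + 1e-12
        # lowest maximising candidate: anything below it must be worse or equal
        assert t <= 0.2

    def test_attains_dense_grid_optimum_on_fuzzed_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.integers(0, 6, rng.integers(1, 7)) / 5.0
            a = rng.integers(0, 6, rng.integers(1, 7)) / 5.0
            t = max_sss_threshold(p, a)
            achieved = np.mean(p >= t) + np.mean(a < t)
            assert achieved == pytest.approx(maxsss_dense_grid(p, a))


class TestBioclim:
    def test_median_scores_one(self):
        train = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        assert score_bioclim(train, [[2.0, 20.0]])[0] == pytest.approx(1.0)

    def test_outside_range_scores_zero(self):
        train = np.array([[1.0], [2.0], [3.0]])
        assert score_bioclim(train, [[99.0]])[0] == 0.0

    def test_hand_percentile(self):
        # train {1..5}, query 2: p = (1 + 0.5)/5 = 0.3 -> score 0.6
        train = np.arange(1.0, 6.0).reshape(-1, 1)
        assert score_bioclim(train, [[2.0]])[0] == pytest.approx(0.6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(20, 3))
        query = rng.normal(size=(5, 3))
        base = score_bioclim(train, query)
        scale = np.array([3.0, 0.5, 10.0])
        shift = np.array([-1.0, 4.0, 0.0])
        mapped = score_bioclim(train * scale + shift, query * scale + shift)
        np.testing.assert_allclose(mapped, base)


class TestDomain:
    def test_self_similarity(self):
        train = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert score_domain(train, [[1.0, 2.0]])[0] == pytest.approx(1.0)

    def test_hand_gower(self):
        # ranges 10 and 2; nearest diffs 1 and 1 -> mean(0.1, 0.5) = 0.3
        train = np.array([[0.0, 0.0], [10.0, 2.0]])
        score = score_domain(train, [[1.0, 1.0]])[0]
        assert score == pytest.approx(0.7)

    def test_total_mismatch_scores_zero(self):
        train = np.array([[0.0], [1.0]])
        assert score_domain(train, [[5.0]])[0] == 0.0

    def test_categorical_mismatch_counts_as_one(self):
        train = np.array([[0.0]])
        same = score_domain(train, [[0.0]], train_cat=np.array([2]), query_cat=np.array([2]))
        diff = score_domain(train, [[0.0]], train_cat=np.array([2]), query_cat=np.array([3]))
        assert same[0] == pytest.approx(1.0)
        assert diff[0] == pytest.approx(0.5)  # one of two variables mismatches

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(15, 2))
        query = rng.normal(size=(6, 2))
        base = score_domain(train, query)
        mapped = score_domain(train * 7.0 + 3.0, query * 7.0 + 3.0)
        np.testing.assert_allclose(mapped, base, atol=1e-12)


class TestMahalanobis:
    def test_training_mean_scores_one(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(30, 3))
        mu = train.mean(axis=0)
        assert score_mahalanobis(train, [mu])[0] == pytest.approx(1.0)

    def test_identity_covariance_unit_step(self):
        # construct a sample with exactly identity covariance and zero mean
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        train = base * np.sqrt(3 / 2)  # per-column var = 2a^2/3 = 1 (ddof=1)
        q = train.mean(axis=0) + np.array([1.0, 0.0])
        assert score_mahalanobis(train, [q], ridge=0.0)[0] == pytest.approx(0.5, rel=1e-6)

    def test_matches_explicit_quadratic_form(self):
        train = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        q = np.array([1.5, 0.2])
        mu = train.mean(axis=0)
        cov = np.cov(train, rowvar=False)
        d2 = (q - mu) @ np.linalg.inv(cov) @ (q - mu)
        got = score_mahalanobis(train, [q], ridge=0.0)[0]
        assert got == pytest.approx(1.0 / (1.0 + d2), rel=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        train = rng.normal(size=(40, 3))
        query = rng.normal(size=(5, 3))
        base = score_mahalanobis(train, query, ridge=0.0)
        A = np.array([[2.0, 0.0, 0.0], [0.0, -3.0, 0.0], [0.0, 0.0, 0.5]])
        mapped = score_mahalanobis(train @ A, query @ A, ridge=0.0)
        np.testing.assert_allclose(mapped, base, rtol=1e-8)


class TestGLMSelection:
    def test_strong_predictor_recovered(self):
        rng = np.random.default_rng(10)
        n = 400
        X = rng.normal(size=(n, 4))
        eta = 2.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        scorer, selected = fit_score_glm(X, y, ["a", "b", "c", "d"])
        assert "b" in selected
        # recovered slope sign positive: score increases with the predictor
        lo = scorer(np.array([[0.0, -2.0, 0.0, 0.0]]))[0]
        hi = scorer(np.array([[0.0, 2.0, 0.0, 0.0]]))[0]
        assert hi > lo

    def test_pure_noise_selects_intercept_only_mostly(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 3))
            y = (rng.random(120) < 0.5).astype(float)
            _, selected = fit_score_glm(X, y)
            hits += not selected
        assert hits >= 6

    def test_empty_candidate_list_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        y = np.array([0.0, 1.0] * 10)
        scorer, selected = fit_score_glm(np.empty((20, 0)), y)
        assert selected == []
        np.testing.assert_allclose(scorer(np.empty((3, 0))), [0.5, 0.5, 0.5], atol=1e-6)


class TestMLScorers:
    @pytest.mark.parametrize("algorithm", ["random_forest", "svm", "maxent_like"])
    def test_separable_data_perfect_train_auc(self, algorithm):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        scorer = fit_score_ml(algorithm, X, y, rng=np.random.default_rng(0))
        s = scorer(X)
        assert auc(s[y == 1], s[y == 0]) == 1.0

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(13)
        aucs = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 3))
            y = r.permutation(np.repeat([0, 1], 100))
            tr, te = np.arange(0, 150), np.arange(150, 200)
            scorer = fit_score_ml("random_forest", X[tr], y[tr], rng=r)
            s = scorer(X[te])
            aucs.append(auc(s[y[te] == 1], s[y[te] == 0]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_step_signal_rf_beats_intercept(self):
        rng = np.random.default_rng(14)
        n = 300
        X = rng.uniform(-1, 1, (n, 1))
        y = (X[:, 0] > 0.2).astype(int)
        flip = rng.random(n) < 0.1
        y[flip] = 1 - y[flip]
        tr = np.arange(0, 225)
        te = np.arange(225, n)
        scorer = fit_score_ml("random_forest", X[tr], y[tr], rng=rng)
        s = scorer(X[te])
        rf_auc = auc(s[y[te] == 1], s[y[te] == 0])
        assert rf_auc > 0.6  # intercept-only would give 0.5

    def test_single_class_raises(self):
        with pytest.raises(Exception):
            fit_score_ml("svm", np.zeros((10, 2)), np.zeros(10))


class TestSSBAdjust:
    def test_balanced_geometry_unchanged(self):
        train = np.array([[0.0, 0.0]])
        test_p = np.array([[1.0, 0.0], [0.0, 1.0]])
        test_a = np.array([[1.0, 0.0], [0.0, -1.0], [-1.0, 0.0]])
        keep, ssb = ssb_adjust(train, test_p, test_a, np.random.default_rng(0))
        assert ssb == pytest.approx(1.0)
        np.testing.assert_array_equal(keep, [0, 1, 2])

    def test_matching_brings_absence_distances_closer(self):
        """Constructed geometry: presences near training data, absences far;
        the matched subset must have near-presence distance statistics."""
        rng = np.random.default_rng(1)
        train = np.zeros((1, 2))
        test_p = rng.normal(0, 1.0, (10, 2))
        near = rng.normal(0, 1.2, (10, 2))
        far = rng.normal(0, 1.0, (10, 2)) + 30.0
        test_a = np.vstack([near, far])
        keep, ssb = ssb_adjust(train, test_p, test_a, rng)
        assert ssb < 1.0
        assert len(keep) == 10
        d_p = np.linalg.norm(test_p, axis=1).mean()
        d_kept = np.linalg.norm(test_a[keep], axis=1).mean()
        d_all = np.linalg.norm(test_a, axis=1).mean()
        assert abs(d_kept - d_p) < abs(d_all - d_p)

    def test_single_pair_trivially_matched(self):
        keep, _ = ssb_adjust(
            np.zeros((1, 2)),
            np.array([[1.0, 0.0]]),
            np.array([[5.0, 0.0], [1.2, 0.0]]),
            np.random.default_rng(0),
        )
        assert len(keep) == 1 and keep[0] == 1

    def test_fewer_absences_than_presences_uses_all(self):
        with pytest.warns(UserWarning):
            keep, _ = ssb_adjust(
                np.zeros((1, 2)),
                np.array([[1.0, 0.0], [0.5, 0.0]]),
                np.array([[9.0, 0.0]]),
                np.random.default_rng(0),
            )
        assert len(keep) == 1
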