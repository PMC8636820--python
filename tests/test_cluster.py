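"""Sparse k-means core: weight update oracle, reduction identities,
robust trimming, and the weighted objective."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from plasticlust import (
    ExpressionDataset,
    robust_sparse_kmeans,
    sparse_kmeans,
    update_weights,
    weight_transform,
    wwss,
)
from plasticlust.dataset import zscore
from plasticlust.errors import DegenerateDataError, ParameterError


# ---------------------------------------------------------------------------
# update_weights
# ---------------------------------------------------------------------------

def brute_force_weights(bcss, l1_bound, step=1e-4):
    """Grid-search maximiser of w.b over the L1/L2/positivity constraints
    for two features: walk w1, set w2 to the largest feasible value."""
    b = np.asarray(bcss, float)
    assert b.size == 2
    best, best_obj = None, -np.inf
    for w1 in np.arange(0.0, 1.0 + step, step):
        w2 = min(l1_bound - w1, math.sqrt(max(0.0, 1.0 - w1**2)))
        if w2 < 0:
            continue
        obj = b[0] * w1 + b[1] * w2
        if obj > best_obj:
            best_obj, best = obj, (w1, w2)
    return np.array(best), best_obj


class TestUpdateWeights:
    def test_symmetric_bcss_gives_uniform_weights(self):
        w = update_weights(np.array([3.0, 3.0, 3.0, 3.0]), 2.0)
        assert np.allclose(w, 0.5, atol=1e-8)

    def test_two_feature_case_matches_grid_search(self):
        w = update_weights(np.array([4.0, 1.0]), 1.1)
        w_star, obj_star = brute_force_weights([4.0, 1.0], 1.1)
        obj = 4.0 * w[0] + 1.0 * w[1]
        assert obj >= obj_star - 1e-3
        assert np.allclose(w, w_star, atol=1e-3)

    def test_single_informative_feature_takes_all_weight(self):
        w = update_weights(np.array([1.0, 0.0, 0.0]), 1.2)
        assert np.allclose(w, [1.0, 0.0, 0.0], atol=1e-8)

    def test_all_nonpositive_bcss_raises(self):
        with pytest.raises(DegenerateDataError):
            update_weights(np.array([0.0, -1.0, 0.0]), 1.5)

    @settings(max_examples=50, deadline=None)
    @given(
        b=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12).filter(
            lambda v: max(v) > 0
        ),
        s_frac=st.floats(0.05, 1.0),
    )
    def test_constraints_always_hold(self, b, s_frac):
        p = len(b)
        s = 1.0 + s_frac * (math.sqrt(p) - 1.0) + 1e-6
        w = update_weights(np.array(b), s)
        assert np.all(w >= 0)
        # the maximiser sits on the unit sphere except in the tied-maxima
        # corner, where it sits inside the sphere at the L1 bound
        assert np.linalg.norm(w) <= 1.0 + 1e-8
        assert w.sum() <= s + 1e-8
        assert np.linalg.norm(w) > 1.0 - 1e-8 or abs(w.sum() - s) < 1e-6


# ---------------------------------------------------------------------------
# sparse_kmeans
# ---------------------------------------------------------------------------

class TestSparseKMeans:
    def test_recovers_planted_two_cluster_partition(self, two_cluster_toy):
        ds, truth = two_cluster_toy
        res = sparse_kmeans(ds, k=2, l1_bound=1.5, seed=0)
        assert adjusted_rand_score(truth, res.assignments) == 1.0
        assert res.weights[0] > 0.9
        assert not res.outlier_flags.any()
        assert res.alpha == 0.0

    def test_inactive_penalty_keeps_all_features_and_kmeans_labels(self, two_cluster_toy):
        # at l1_bound = sqrt(p) the lasso constraint is inactive: no weight
        # is thresholded to zero (weights equal the normalised per-feature
        # between-cluster SS) and the partition agrees with standard k-means
        # (on a toy where every feature is informative, so the reweighting
        # cannot move the partition away from the k-means one)
        rng = np.random.default_rng(21)
        values = np.vstack([
            rng.normal(0.0, 0.4, (8, 4)),
            rng.normal(4.0, 0.4, (8, 4)) * np.array([1, -1, 1, -1]),
        ])
        ds = ExpressionDataset(
            values=values,
            feature_names=[f"p{j}" for j in range(4)],
            sample_ids=[f"s{i}" for i in range(16)],
            ages=np.linspace(0.1, 70, 16),
        )
        p = ds.n_features
        res = sparse_kmeans(ds, k=2, l1_bound=math.sqrt(p), seed=3)
        assert np.all(res.weights > 0)
        from plasticlust.cluster import _bcss_per_feature

        bcss = _bcss_per_feature(
            zscore(ds.values), res.assignments, np.ones(ds.n_samples, dtype=bool)
        )
        expected = np.maximum(bcss, 0) / np.linalg.norm(np.maximum(bcss, 0))
        assert np.allclose(res.weights, expected, atol=1e-3)
        km = KMeans(n_clusters=2, n_init=10, random_state=3).fit(zscore(ds.values))
        assert adjusted_rand_score(km.labels_, res.assignments) == 1.0

    def test_k_equals_n_gives_zero_wwss(self):
        rng = np.random.default_rng(5)
        ds = ExpressionDataset(
            values=rng.normal(0, 1, (6, 3)),
            feature_names=["a", "b", "c"],
            sample_ids=[f"s{i}" for i in range(6)],
            ages=np.linspace(1, 60, 6),
        )
        res = sparse_kmeans(ds, k=6, l1_bound=1.5, seed=0)
        assert len(np.unique(res.assignments)) == 6
        assert res.wwss == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_partition_search_on_tiny_instance(self):
        # brute force over all 2-cluster set partitions of 7 samples under
        # the same weighted between-cluster objective
        rng = np.random.default_rng(11)
        X = np.vstack([
            rng.normal(0, 0.5, (4, 2)),
            rng.normal(4, 0.5, (3, 2)),
        ])
        Xz = zscore(X)
        s = 1.3

        def objective(labels):
            labels = np.asarray(labels)
            mu = Xz.mean(axis=0)
            tss = ((Xz - mu) ** 2).sum(axis=0)
            wss = np.zeros(Xz.shape[1])
            for c in set(labels):
                m = Xz[labels == c]
                wss += ((m - m.mean(axis=0)) ** 2).sum(axis=0)
            bcss = tss - wss
            if bcss.max() <= 0:
                return -np.inf
            w = update_weights(bcss, s)
            return float(w @ bcss)

        best_obj = -np.inf
        for pattern in itertools.product([0, 1], repeat=6):
            labels = np.array((0,) + pattern)
            if len(set(labels)) < 2:
                continue
            best_obj = max(best_obj, objective(labels))

        ds = ExpressionDataset(
            values=X,
            feature_names=["a", "b"],
            sample_ids=[f"s{i}" for i in range(7)],
            ages=np.linspace(1, 60, 7),
        )
        res = sparse_kmeans(ds, k=2, l1_bound=s, n_starts=20, seed=0)
        assert res.objective == pytest.approx(best_obj, rel=1e-6)

    def test_parameter_errors(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        with pytest.raises(ParameterError):
            sparse_kmeans(ds, k=ds.n_samples + 1, l1_bound=1.5)
        with pytest.raises(ParameterError):
            sparse_kmeans(ds, k=2, l1_bound=0.9)
        with pytest.raises(ParameterError):
            sparse_kmeans(ds, k=2, l1_bound=math.sqrt(ds.n_features) + 0.5)

    def test_constant_matrix_raises_degenerate(self):
        ds = ExpressionDataset(
            values=np.ones((8, 3)),
            feature_names=["a", "b", "c"],
            sample_ids=[f"s{i}" for i in range(8)],
            ages=np.linspace(1, 60, 8),
        )
        with pytest.raises(DegenerateDataError):
            sparse_kmeans(ds, k=2, l1_bound=1.5)

    def test_objective_ascends_across_alternations(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        res = sparse_kmeans(ds, k=2, l1_bound=1.5, seed=1)
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) >= -1e-9 * max(1.0, hist.max()))

    def test_sparsity_monotone_in_l1_bound(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        zeros = []
        for s in [1.1, 1.5, 2.0, 2.5, 3.0]:
            res = sparse_kmeans(ds, k=2, l1_bound=s, seed=4)
            zeros.append(int(np.sum(res.weights < 1e-10)))
        assert all(a >= b for a, b in zip(zeros, zeros[1:]))


# ---------------------------------------------------------------------------
# robust_sparse_kmeans
# ---------------------------------------------------------------------------

class TestRobustSparseKMeans:
    def test_alpha_zero_reduces_to_sparse_kmeans_bitwise(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        a = sparse_kmeans(ds, k=2, l1_bound=1.5, seed=9)
        b = robust_sparse_kmeans(ds, k=2, l1_bound=1.5, alpha=0.0, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.weights, b.weights)
        assert a.wwss == b.wwss

    def test_flags_planted_outliers_and_recovers_partition(self, planted_outlier_toy):
        ds, truth = planted_outlier_toy
        res = robust_sparse_kmeans(ds, k=3, l1_bound=1.8, alpha=0.1, seed=0)
        planted = truth == 0
        assert res.outlier_flags[planted].all()
        clean = ~planted
        assert adjusted_rand_score(truth[clean], res.assignments[clean]) == 1.0
        assert len(np.unique(res.assignments)) == 3

    def test_no_singleton_cluster_where_sparse_kmeans_makes_one(self):
        # one tight cloud, a second small group, and a single extreme point
        # that seeds a singleton under the non-robust variant
        rng = np.random.default_rng(2)
        values = np.vstack([
            rng.normal(0, 0.3, (6, 3)),
            rng.normal(3, 0.3, (5, 3)),
            np.array([[80.0, -80.0, 80.0]]),
        ])
        ds = ExpressionDataset(
            values=values,
            feature_names=["a", "b", "c"],
            sample_ids=[f"s{i}" for i in range(12)],
            ages=np.linspace(1, 60, 12),
        )
        plain = sparse_kmeans(ds, k=2, l1_bound=1.5, seed=0)
        sizes_plain = np.bincount(plain.assignments)[1:]
        assert sizes_plain.min() == 1  # the failure mode being addressed
        robust = robust_sparse_kmeans(ds, k=2, l1_bound=1.5, alpha=0.1, seed=0)
        sizes_robust = np.bincount(robust.assignments)[1:]
        assert sizes_robust.min() >= 2

    def test_alpha_range_validated(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        with pytest.raises(ParameterError):
            robust_sparse_kmeans(ds, k=2, l1_bound=1.5, alpha=0.5)

    def test_norm_invariants_hold(self, planted_outlier_toy):
        ds, _ = planted_outlier_toy
        res = robust_sparse_kmeans(ds, k=3, l1_bound=1.8, alpha=0.1, seed=5)
        assert abs(np.linalg.norm(res.weights) - 1.0) < 1e-8
        assert res.weights.sum() <= res.l1_bound + 1e-8
        assert np.all(res.assignments >= 1)
        assert len(np.unique(res.assignments)) == 3  # no empty cluster


# ---------------------------------------------------------------------------
# wwss and weight_transform
# ---------------------------------------------------------------------------

class TestWWSS:
    def test_six_point_toy_matches_direct_summation(self):
        values = np.array(
            [[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [4.0, 5.0], [5.0, 4.0], [4.5, 4.5]]
        )
        labels = np.array([1, 1, 1, 2, 2, 2])
        w = np.array([0.8, 0.6])
        expected = 0.0
        for c in (1, 2):
            m = values[labels == c]
            expected += (w * ((m - m.mean(axis=0)) ** 2).sum(axis=0)).sum()
        got = wwss(values, labels, w, standardize=False)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_cluster_equals_weighted_total_dispersion(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (9, 3))
        w = np.full(3, 1 / np.sqrt(3))
        labels = np.ones(9, dtype=int)
        total = (w * ((X - X.mean(axis=0)) ** 2).sum(axis=0)).sum()
        assert wwss(X, labels, w, standardize=False) == pytest.approx(total)

    def test_all_singletons_give_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (5, 4))
        labels = np.arange(1, 6)
        assert wwss(X, labels, np.full(4, 0.5), standardize=False) == 0.0

    def test_nested_refinement_does_not_increase_wwss(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (12, 4))
        w = np.full(4, 0.5)
        coarse = np.array([1] * 6 + [2] * 6)
        fine = np.array([1] * 3 + [3] * 3 + [2] * 3 + [4] * 3)
        assert wwss(X, fine, w, standardize=False) <= wwss(X, coarse, w, standardize=False) + 1e-12

    def test_invalid_labels_raise(self):
        X = np.zeros((4, 2)) + np.arange(4)[:, None]
        with pytest.raises(ParameterError):
            wwss(X, np.array([0, 1, 1, 2]), np.array([1.0, 0.0]), standardize=False)


class TestWeightTransform:
    def test_unit_weights_are_identity(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        out = weight_transform(ds, np.ones(ds.n_features))
        assert np.array_equal(out, ds.values)

    def test_zero_weight_zeroes_column(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        w = np.ones(ds.n_features)
        w[3] = 0.0
        out = weight_transform(ds, w)
        assert np.all(out[:, 3] == 0.0)

    def test_matches_elementwise_product(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (4, 3))
        w = np.array([0.2, 0.5, 1.5])
        assert np.allclose(weight_transform(X, w), X * w)

    def test_length_mismatch_raises(self, two_cluster_toy):
        ds, _ = two_cluster_toy
        with pytest.raises(ParameterError):
            weight_transform(ds, np.ones(ds.n_features - 1))
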