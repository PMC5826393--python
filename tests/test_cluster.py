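"""K-means, the gap statistic, PVE, silhouette and split-half validation."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import norm

from authortopics._seeds import child_seed
from authortopics.cluster import (
    GapCurve,
    gap_statistic,
    kmeans,
    pve,
    select_k_compound,
    select_k_gap,
    silhouette_mean,
    split_half_validation,
)


class TestKmeans:
    def test_k_equals_n_gives_zero_within_ss(self, rng):
        X = rng.random((6, 2))
        assert kmeans(X, 6, seed=0).within_ss == pytest.approx(0.0, abs=1e-12)

    def test_obvious_two_cluster_optimum(self):
        X = np.array([[0.0], [1.0], [100.0], [101.0]])
        sol = kmeans(X, 2, seed=0)
        groups = {tuple(sorted(np.where(sol.assignments == c)[0])) for c in range(2)}
        assert groups == {(0, 1), (2, 3)}
        assert sol.within_ss == pytest.approx(1.0)

    def test_within_ss_equals_exhaustive_minimum(self, rng):
        """Brute force over all 2-partitions of six 2D points."""
        X = rng.random((6, 2)) * 3
        sol = kmeans(X, 2, n_restarts=20, seed=1)
        best = np.inf
        idx = range(6)
        for size in range(1, 6):
            for left in itertools.combinations(idx, size):
                right = [i for i in idx if i not in left]
                wss = sum(
                    ((X[list(g)] - X[list(g)].mean(axis=0)) ** 2).sum()
                    for g in (left, right)
                )
                best = min(best, wss)
        assert sol.within_ss == pytest.approx(best, abs=1e-9)

    def test_centroids_are_cluster_means(self, rng):
        X = rng.random((30, 3))
        sol = kmeans(X, 4, seed=2)
        for c in range(4):
            np.testing.assert_allclose(
                sol.centroids[c], X[sol.assignments == c].mean(axis=0), atol=1e-9
            )

    def test_k_larger_than_n_raises(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.random((4, 2)), 5, seed=0)


class TestPve:
    def test_single_cluster_is_zero(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert pve(kmeans(X, 1, seed=0), X) == pytest.approx(0.0, abs=1e-12)

    def test_saturated_partition_is_one(self, rng):
        X = rng.random((5, 2))
        assert pve(kmeans(X, 5, seed=0), X) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_fraction(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        sol = kmeans(X, 2, seed=0)
        assert pve(sol, X) == pytest.approx(100.0 / 104.0, abs=1e-12)

    def test_zero_total_ss_raises(self):
        X = np.ones((4, 2))
        sol = kmeans(X, 2, seed=0)
        with pytest.raises(ValueError, match="variance"):
            pve(sol, X)

    def test_matches_brute_force_on_small_instance(self, rng):
        X = rng.random((10, 3))
        sol = kmeans(X, 3, seed=1)
        total = ((X - X.mean(axis=0)) ** 2).sum()
        within = sum(
            ((X[sol.assignments == c] - X[sol.assignments == c].mean(axis=0)) ** 2).sum()
            for c in range(3)
        )
        assert pve(sol, X) == pytest.approx((total - within) / total, abs=1e-9)


class TestSilhouette:
    def test_two_tight_far_clusters_near_one(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        sol = kmeans(X, 2, seed=0)
        # hand per-point: point 0 has a=1, b=(10+11)/2 -> s=9.5/10.5;
        # point 1 has a=1, b=(9+10)/2 -> s=8.5/9.5; clusters symmetric
        expected = np.mean([9.5 / 10.5, 8.5 / 9.5])
        assert silhouette_mean(sol, X) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_reimplementation(self, rng):
        X = rng.random((12, 2))
        sol = kmeans(X, 3, seed=3)
        labels = sol.assignments
        D = cdist(X, X)
        per_point = []
        for i in range(len(X)):
            same = (labels == labels[i]) & (np.arange(len(X)) != i)
            if not same.any():
                per_point.append(0.0)
                continue
            a = D[i, same].mean()
            b = min(
                D[i, labels == c].mean() for c in set(labels) if c != labels[i]
            )
            per_point.append((b - a) / max(a, b))
        per_point = np.asarray(per_point)
        expected = np.mean(
            [per_point[labels == c].mean() for c in sorted(set(labels))]
        )
        assert silhouette_mean(sol, X) == pytest.approx(expected, abs=1e-9)

    def test_k_below_two_raises(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError):
            silhouette_mean(kmeans(X, 1, seed=0), X)


class TestGapStatistic:
    def test_uniform_data_gap_near_zero(self, rng):
        X = rng.random((120, 2))
        curve = gap_statistic(X, ks=[2, 3, 4], B=10, seed=0)
        for g, s in zip(curve.gap, curve.null_sd):
            assert abs(g) < 3 * s + 0.15

    def test_three_blobs_selects_three(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.vstack([c + 0.3 * rng.standard_normal((40, 2)) for c in centers])
        curve = gap_statistic(X, ks=[1, 2, 3, 4, 5, 6], B=10, seed=1)
        assert select_k_gap(curve) == 3

    def test_matches_independent_reimplementation(self, rng):
        """Same seed chain, independently coded gap computation."""
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.vstack([c + 0.3 * rng.standard_normal((25, 2)) for c in centers])
        ks, B, seed = [2, 3, 4], 5, 9
        curve = gap_statistic(X, ks=ks, B=B, seed=seed)

        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_rng = np.random.default_rng(child_seed(seed, "gap-ref"))
        refs = [lo + (hi - lo) * ref_rng.random(X.shape) for _ in range(B)]
        for i, k in enumerate(ks):
            log_w = np.log(kmeans(X, k, seed=child_seed(seed, "gap-data", k)).within_ss)
            ref_log = np.array(
                [
                    np.log(
                        kmeans(refs[b], k, seed=child_seed(seed, "gap-b", k, b)).within_ss
                    )
                    for b in range(B)
                ]
            )
            assert curve.gap[i] == pytest.approx(ref_log.mean() - log_w, abs=1e-9)
            assert curve.null_sd[i] == pytest.approx(
                ref_log.std() * np.sqrt(1 + 1 / B), abs=1e-9
            )

    def test_invariant_to_point_order(self, rng):
        X = rng.random((50, 3))
        perm = rng.permutation(50)
        a = gap_statistic(X, ks=[2, 3], B=5, seed=4)
        b = gap_statistic(X[perm], ks=[2, 3], B=5, seed=4)
        # k-means restarts may land in slightly different local optima when
        # the row order changes; the gap values must agree statistically
        np.testing.assert_allclose(a.gap, b.gap, atol=0.05)

    def test_degenerate_dimension_held_constant(self, rng):
        X = np.column_stack([rng.random(30), np.full(30, 2.5)])
        curve = gap_statistic(X, ks=[2, 3], B=4, seed=5)
        assert np.isfinite(curve.gap).all()

    def test_b_below_two_raises(self, rng):
        with pytest.raises(ValueError):
            gap_statistic(rng.random((10, 2)), ks=[2], B=1, seed=0)


class TestSelectKCompound:
    def test_prefers_larger_k_on_silhouette_near_tie(self):
        # silhouette local maxima at k=2, 10 and 12 (mirroring a low-k
        # maximum with poor PVE and a near-tie between two larger maxima)
        ks = [2, 4, 10, 11, 12]
        curve = GapCurve(ks=ks, gap=[1.0, 1.1, 1.2, 1.25, 1.3],
                         null_sd=[0.01] * 5, B=20)
        pves = [0.1, 0.3, 0.6, 0.62, 0.65]
        sils = [0.52, 0.4, 0.527, 0.51, 0.523]
        k, log = select_k_compound(ks, curve, pves, sils)
        assert k == 12
        assert log["silhouette_maxima"] == [2, 10, 12]
        assert 2 not in log["candidates"]  # killed by the PVE floor


class TestSplitHalf:
    def test_separable_blobs_reach_perfect_accuracy(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))]
        )
        y = np.repeat([0, 1], 30)
        acc, sd, chance = split_half_validation(X, y, n_reps=20, seed=0)
        assert acc > 0.99
        assert chance == pytest.approx(0.5)

    def test_permuted_labels_fall_to_chance(self, rng):
        X = rng.random((80, 3))
        y = rng.permutation(np.repeat([0, 1], 40))
        acc, sd, chance = split_half_validation(X, y, n_reps=30, seed=1)
        assert abs(acc - chance) < max(3 * sd, 0.12)

    def test_accuracy_matches_bayes_boundary(self, rng):
        """1D equal-variance Gaussians: LDA accuracy ~ Phi(delta / 2 sigma)."""
        n, mu, sigma = 400, 1.0, 1.0
        X = np.concatenate(
            [rng.normal(0, sigma, n), rng.normal(mu, sigma, n)]
        ).reshape(-1, 1)
        y = np.repeat([0, 1], n)
        acc, sd, _ = split_half_validation(X, y, n_reps=20, seed=2)
        expected = norm.cdf(mu / (2 * sigma))
        assert acc == pytest.approx(expected, abs=0.04)

    def test_chance_definitions(self, rng):
        X = rng.random((30, 2))
        y = np.array([0] * 20 + [1] * 10)
        _, _, c1 = split_half_validation(X, y, n_reps=2, seed=0)
        _, _, c2 = split_half_validation(X, y, n_reps=2, seed=0, chance="largest_class")
        assert c1 == pytest.approx((2 / 3) ** 2 + (1 / 3) ** 2)
        assert c2 == pytest.approx(2 / 3)

    def test_singleton_class_raises(self, rng):
        X = rng.random((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            split_half_validation(X, y, n_reps=2, seed=0)
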