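"""Four clustering methods against brute-force oracles and known limits."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from adsubtypes import clustering
from adsubtypes.clustering import (
    hamming_kernel,
    negative_squared_distances,
    run_affinity_propagation,
    run_kernel_kmeans,
    run_kmeans,
    run_latent_class,
    select_k,
    sweep_preference,
)


def two_clouds(rng, n_per=4, sep=10.0, d=2):
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(0, 1, (n_per, d)) + sep
    return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)


def brute_force_two_partition_wss(X):
    """Minimum WSS over every 2-partition of the points (oracle, n small)."""
    n = len(X)
    best = np.inf
    for size in range(1, n // 2 + 1):
        for subset in itertools.combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            wss = 0.0
            for part in (X[mask], X[~mask]):
                wss += ((part - part.mean(axis=0)) ** 2).sum()
            best = min(best, wss)
    return best


class TestKMeans:
    def test_two_clouds_match_exhaustive_partition(self, rng):
        X, truth = two_clouds(rng, n_per=4)
        sol = run_kmeans(X, 2, n_restarts=20, seed=0)
        assert sol.objective == pytest.approx(
            brute_force_two_partition_wss(X), rel=1e-12)
        assert (sol.labels == truth).all() or (sol.labels == 1 - truth).all()

    def test_k_equals_n_gives_zero_wss(self, rng):
        X = rng.normal(size=(6, 3))
        sol = run_kmeans(X, 6, n_restarts=5, seed=0)
        assert sol.objective == pytest.approx(0.0, abs=1e-20)

    def test_best_of_restarts_no_worse_than_single(self, rng):
        X = rng.normal(size=(60, 2))
        many = run_kmeans(X, 6, n_restarts=50, seed=3)
        one = run_kmeans(X, 6, n_restarts=1, seed=3)
        assert many.objective <= one.objective + 1e-12

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 3))
        a = run_kmeans(X, 4, n_restarts=10, seed=7)
        b = run_kmeans(X, 4, n_restarts=10, seed=7)
        assert (a.labels == b.labels).all()
        assert a.objective == b.objective

    def test_objective_history_monotone(self, rng):
        X = rng.normal(size=(200, 4))
        sol = run_kmeans(X, 5, n_restarts=3, seed=1)
        hist = np.array(sol.extras["wss_history"])
        assert (np.diff(hist) <= 1e-9).all()

    def test_matches_sklearn_objective(self, rng):
        """Independent cross-check: same best WSS as sklearn's k-means."""
        from sklearn.cluster import KMeans

        X, _ = two_clouds(rng, n_per=20, sep=6.0, d=3)
        ours = run_kmeans(X, 2, n_restarts=20, seed=0)
        sk = KMeans(n_clusters=2, n_init=20, random_state=0).fit(X)
        assert ours.objective == pytest.approx(sk.inertia_, rel=1e-9)

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            run_kmeans(X, 6, seed=0)


class TestSelectK:
    def test_five_planted_gaussians_chosen_by_all_rules(self, rng):
        centers = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0],
                            [0, 0, 20], [20, 20, 20]], dtype=float)
        X = np.vstack([c + rng.normal(0, 1, (40, 3)) for c in centers])
        report = select_k(X, range(2, 9), n_restarts=10, seed=0)
        assert report.chosen_k == 5
        assert report.rule_choices["wss_elbow"] == 5
        assert report.rule_choices["silhouette"] == 5
        assert report.rule_choices["bic"] == 5

    def test_single_cloud_flags_no_structure(self, rng):
        X = rng.normal(size=(300, 3))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            report = select_k(X, range(2, 7), n_restarts=5, seed=0)
        assert report.no_structure

    def test_boundary_range_still_finds_k(self, rng):
        centers = np.array([[0.0, 0.0], [15.0, 0.0], [0.0, 15.0]])
        X = np.vstack([c + rng.normal(0, 0.5, (30, 2)) for c in centers])
        report = select_k(X, range(2, 4), n_restarts=10, seed=0)
        assert report.chosen_k == 3

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_k(np.ones((20, 2)), range(2, 5))

    def test_wss_non_increasing_in_k(self, rng):
        X = rng.normal(size=(100, 3))
        report = select_k(X, range(2, 8), n_restarts=10, seed=0)
        wss = [report.total_wss[k] for k in report.candidate_ks]
        assert (np.diff(wss) <= 1e-6).all()


class TestHammingKernel:
    def test_identical_rows_unit_similarity(self):
        codes = np.tile([0, 1, 2, 0, 1], (4, 1))
        K = hamming_kernel(codes, gamma=0.3)
        np.testing.assert_allclose(K, 1.0)

    def test_all_different_rows_closed_form(self):
        codes = np.array([[0] * 7, [1] * 7])
        K = hamming_kernel(codes, gamma=0.2)
        assert K[0, 1] == pytest.approx(np.exp(-0.2 * 7), rel=1e-12)

    def test_positive_semidefinite(self, rng):
        codes = rng.integers(0, 3, size=(20, 21))
        K = hamming_kernel(codes)
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() >= -1e-10

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            hamming_kernel(np.zeros((3, 4), dtype=int), gamma=0.0)

    def test_feature_matrix_distance_counts_parents(self, small_features):
        fm, _, _ = small_features
        K = hamming_kernel(fm, gamma=1.0)
        codes = fm.parent_codes().to_numpy()
        i, j = 0, 1
        d = (codes[i] != codes[j]).sum()
        assert K[i, j] == pytest.approx(np.exp(-d), rel=1e-10)


class TestKernelKMeans:
    def test_linear_kernel_equals_plain_kmeans(self, rng):
        """With K = X X^T and a shared initialisation the kernelised updates
        reproduce plain Lloyd's labels exactly."""
        X, _ = two_clouds(rng, n_per=25, sep=4.0, d=3)
        K = X @ X.T
        from sklearn.cluster import kmeans_plusplus

        centers, _ = kmeans_plusplus(X, n_clusters=3, random_state=5)
        init_labels = cdist(X, centers, "sqeuclidean").argmin(axis=1)
        plain = run_kmeans(X, 3, init_centers=centers)
        kern = run_kernel_kmeans(K, 3, init_labels=init_labels)
        assert (plain.labels == kern.labels).all()

    def test_two_categorical_blocks_recovered(self, rng):
        base = rng.integers(0, 2, size=21)
        flipped = base.copy()
        flipped[:16] = 1 - flipped[:16]  # differ in 16 of 21 variables
        codes = np.vstack([np.tile(base, (15, 1)), np.tile(flipped, (15, 1))])
        noise = rng.random(codes.shape) < 0.05
        codes = np.where(noise, 1 - codes, codes)
        K = hamming_kernel(codes)
        sol = run_kernel_kmeans(K, 2, n_restarts=10, seed=0)
        truth = np.array([0] * 15 + [1] * 15)
        assert ((sol.labels == truth).all() or (sol.labels == 1 - truth).all())

    def test_single_cluster_objective_is_total_kernel_variance(self, rng):
        codes = rng.integers(0, 2, size=(12, 6))
        K = hamming_kernel(codes)
        sol = run_kernel_kmeans(K, 1, n_restarts=1, seed=0)
        expected = float(np.trace(K)) - K.sum() / len(K)
        assert sol.objective == pytest.approx(expected, rel=1e-12)

    def test_asymmetric_kernel_rejected(self):
        K = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            run_kernel_kmeans(K, 1)

    def test_deterministic_under_seed(self, rng):
        codes = rng.integers(0, 2, size=(40, 8))
        K = hamming_kernel(codes)
        a = run_kernel_kmeans(K, 3, n_restarts=5, seed=2)
        b = run_kernel_kmeans(K, 3, n_restarts=5, seed=2)
        assert (a.labels == b.labels).all()


def exhaustive_affinity_oracle(S, preference, max_k=None):
    """Best exemplar set by exhaustive search (oracle for small n)."""
    n = S.shape[0]
    S = S.copy()
    np.fill_diagonal(S, preference)
    best, best_set = -np.inf, None
    for k in range(1, (max_k or n) + 1):
        for E in itertools.combinations(range(n), k):
            E = list(E)
            total = S[:, E].max(axis=1)
            for e in E:
                total[e] = S[e, e]
            val = total.sum()
            if val > best:
                best, best_set = val, set(E)
    return best_set, best


class TestAffinityPropagation:
    def triads(self, rng):
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        return np.vstack([c + rng.normal(0, 0.3, (3, 2)) for c in centers])

    def test_three_triads_match_exhaustive_exemplar_search(self, rng):
        X = self.triads(rng)
        S = negative_squared_distances(X)
        pref = np.median(S[~np.eye(9, dtype=bool)])
        sol = run_affinity_propagation(S, preference=pref)
        oracle_set, _ = exhaustive_affinity_oracle(S, pref)
        assert sol.k == 3
        assert set(sol.extras["exemplars"]) == oracle_set
        truth = np.repeat([0, 1, 2], 3)
        for g in range(3):
            assert len(np.unique(sol.labels[truth == g])) == 1

    def test_huge_preference_gives_singletons(self, rng):
        X = self.triads(rng)
        S = negative_squared_distances(X)
        sol = run_affinity_propagation(S, preference=1e4)
        assert sol.k == len(X)

    def test_very_negative_preference_gives_one_cluster(self, rng):
        X = self.triads(rng)
        S = negative_squared_distances(X)
        sol = run_affinity_propagation(S, preference=-1e6)
        assert sol.k == 1

    def test_matches_sklearn_on_clear_structure(self, rng):
        """Independent cross-check against sklearn's implementation."""
        from sklearn.cluster import AffinityPropagation

        X = np.vstack([c + rng.normal(0, 0.4, (10, 2))
                       for c in [[0, 0], [12, 0], [0, 12]]])
        S = negative_squared_distances(X)
        pref = np.median(S[~np.eye(len(X), dtype=bool)])
        ours = run_affinity_propagation(S, preference=pref, damping=0.9)
        sk = AffinityPropagation(preference=pref, damping=0.9,
                                 random_state=0).fit(X)
        assert ours.k == len(sk.cluster_centers_indices_)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ours.labels, sk.labels_) == 1.0

    def test_bad_damping_rejected(self):
        with pytest.raises(ValueError):
            run_affinity_propagation(np.zeros((3, 3)), 0.0, damping=0.3)


class TestSweepPreference:
    def test_planted_five_clusters_chosen(self, rng):
        centers = rng.normal(0, 15, (5, 2))
        X = np.vstack([c + rng.normal(0, 0.5, (20, 2)) for c in centers])
        S = negative_squared_distances(X)
        sweep = sweep_preference(S, n_grid=12)
        assert sweep.chosen.k == 5

    def test_single_point_grid_rejected(self, rng):
        S = negative_squared_distances(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            sweep_preference(S, preference_grid=[-1.0])

    def test_net_similarity_non_decreasing_in_k(self, rng):
        X = rng.normal(size=(40, 2))
        S = negative_squared_distances(X)
        sweep = sweep_preference(S, n_grid=10)
        by_k = sweep.rows.groupby("k")["net_similarity"].max().sort_index()
        assert (np.diff(by_k.to_numpy()) >= -1e-9).all()


class TestLatentClass:
    def test_bernoulli_two_classes_bic_and_posteriors(self, rng):
        theta = np.array([[0.9] * 6 + [0.1] * 6, [0.1] * 6 + [0.9] * 6])
        z = rng.integers(0, 2, 400)
        X = (rng.random((400, 12)) < theta[z]).astype(float)
        sol = run_latent_class(X, k_range=range(2, 5), seed=0, mode="bernoulli")
        assert sol.k == 2
        post = sol.extras["posteriors"]
        assert np.mean(post.max(axis=1) > 0.95) > 0.9
        acc = max((sol.labels == z).mean(), (sol.labels != z).mean())
        assert acc > 0.95

    def test_gaussian_mode_recovers_planted_classes(self, rng):
        centers = rng.normal(0, 8, (3, 3))
        z = rng.integers(0, 3, 300)
        X = centers[z] + rng.normal(0, 0.7, (300, 3))
        sol = run_latent_class(X, k_range=range(2, 6), seed=0, mode="gaussian")
        assert sol.k == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(z, sol.labels) > 0.95

    def test_posterior_rows_sum_to_one_and_argmax_labels(self, rng):
        X = rng.normal(size=(100, 2))
        sol = run_latent_class(X, k_range=[3], seed=1, mode="gaussian")
        post = sol.extras["posteriors"]
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)
        assert (sol.labels == post.argmax(axis=1)).all()

    def test_label_switching_invariant_partitions(self, rng):
        """Different seeds may permute class labels but define the same
        partition once aligned."""
        from adsubtypes.evaluation import align_labels

        theta = np.array([[0.95] * 5 + [0.05] * 5, [0.05] * 5 + [0.95] * 5])
        z = rng.integers(0, 2, 300)
        X = (rng.random((300, 10)) < theta[z]).astype(float)
        a = run_latent_class(X, k_range=[2], seed=1, mode="bernoulli")
        b = run_latent_class(X, k_range=[2], seed=99, mode="bernoulli")
        _, aligned = align_labels(a.labels, b.labels)
        assert (aligned == a.labels).all()

    def test_bic_minimised_at_generating_k(self, rng):
        """BIC at the planted k beats k +/- 1 in at least 90% of replicates."""
        theta = np.array([
            [0.9] * 5 + [0.1] * 10,
            [0.1] * 5 + [0.9] * 5 + [0.1] * 5,
            [0.1] * 10 + [0.9] * 5,
        ])
        wins = 0
        reps = 10
        for r in range(reps):
            rr = np.random.default_rng(100 + r)
            z = rr.integers(0, 3, 500)
            X = (rr.random((500, 15)) < theta[z]).astype(float)
            sol = run_latent_class(X, k_range=[2, 3, 4], seed=r, mode="bernoulli")
            bic = sol.extras["bic"]
            wins += bic[3] < bic[2] and bic[3] < bic[4]
        assert wins >= 0.9 * reps

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            run_latent_class(rng.normal(size=(10, 2)), mode="wibble")
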