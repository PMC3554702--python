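"""Unit allocation, spherical k-means against brute-force oracles, max pooling."""

import itertools

import numpy as np
import pytest

from gnosticfield import (
    AllocationPolicy,
    GnosticSet,
    allocate_units,
    fit_gnostic_set,
    set_response,
    spherical_kmeans,
)
from gnosticfield.gnostic_sets import kmeans_objective

from conftest import unit_rows


def brute_force_objective(P, k):
    """Best spherical k-means objective over every assignment of <=12 points.

    For a fixed cluster the optimal centroid is the normalized mean, so the
    summed cosine of a cluster is the norm of its vector sum; the global
    optimum is the max over partitions of the summed norms.
    """
    n = P.shape[0]
    best = -np.inf
    for assign in itertools.product(range(k), repeat=n):
        a = np.array(assign)
        total = 0.0
        for j in range(k):
            sel = P[a == j]
            if len(sel):
                total += np.linalg.norm(sel.sum(axis=0))
        best = max(best, total)
    return best


def _bundles(rng, centers, per_bundle, spread):
    pts = []
    for c in centers:
        pts.append(unit_rows(c + spread * rng.standard_normal((per_bundle, len(c)))))
    return np.vstack(pts)


class TestAllocation:
    def test_tiny_n_stores_the_data(self):
        assert allocate_units(1, 128) == 1
        assert allocate_units(2, 2, AllocationPolicy(alpha=1e9)) == 2

    def test_allocated_fraction_shrinks_with_exposure(self):
        d = 64
        fr = [allocate_units(n, d) / n for n in (10**2, 10**4, 10**6)]
        assert fr[0] > fr[1] > fr[2]

    def test_nondecreasing_in_n_and_capped(self):
        prev = 0
        for n in [1, 2, 5, 10, 100, 1000, 10000]:
            k = allocate_units(n, 16)
            assert prev <= k <= n
            prev = k

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            allocate_units(0, 5)
        with pytest.raises(ValueError):
            AllocationPolicy(alpha=-1.0)


class TestSphericalKMeans:
    def test_single_cluster_is_normalized_mean(self, rng):
        P = unit_rows(rng.standard_normal((10, 4)))
        C = spherical_kmeans(P, 1, seed=0)
        mean_dir = P.mean(axis=0)
        np.testing.assert_allclose(
            C[0], mean_dir / np.linalg.norm(mean_dir), atol=1e-12
        )

    def test_saturation_k_equals_n(self, rng):
        P = unit_rows(rng.standard_normal((6, 3)))
        C = spherical_kmeans(P, 6, seed=3)
        assert kmeans_objective(P, C) == pytest.approx(6.0, abs=1e-9)
        # every point is its own centroid, up to ordering
        match = (C @ P.T).max(axis=1)
        np.testing.assert_allclose(match, 1.0, atol=1e-9)

    def test_antipodal_bundles_match_exhaustive_partition(self, rng):
        theta = rng.uniform(0, 0.05, size=5)
        up = np.column_stack([np.sin(theta), np.cos(theta)])
        down = -np.column_stack([np.sin(theta + 0.02), np.cos(theta + 0.02)])
        P = np.vstack([up, down])
        C = spherical_kmeans(P, 2, seed=1)
        assert kmeans_objective(P, C) == pytest.approx(
            brute_force_objective(P, 2), abs=1e-9
        )
        for bundle in (up, down):
            m = bundle.mean(axis=0)
            m /= np.linalg.norm(m)
            angle = np.arccos(np.clip((C @ m).max(), -1, 1))
            assert angle < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_brute_force_on_separated_bundles(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.eye(3)
        P = _bundles(rng, centers, per_bundle=3, spread=0.05)
        C = spherical_kmeans(P, 3, seed=seed)
        assert kmeans_objective(P, C) == pytest.approx(
            brute_force_objective(P, 3), abs=1e-9
        )

    def test_deterministic_given_seed(self, rng):
        P = unit_rows(rng.standard_normal((30, 5)))
        C1 = spherical_kmeans(P, 4, seed=9)
        C2 = spherical_kmeans(P, 4, seed=9)
        np.testing.assert_array_equal(C1, C2)

    def test_objective_nondecreasing_over_iterations(self, rng):
        P = unit_rows(rng.standard_normal((40, 4)))
        objs = [
            kmeans_objective(P, spherical_kmeans(P, 5, seed=2, max_iter=i))
            for i in (1, 3, 10, 100)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_invalid_inputs(self, rng):
        P = unit_rows(rng.standard_normal((4, 3)))
        with pytest.raises(ValueError):
            spherical_kmeans(P, 5, seed=0)  # k > distinct points
        with pytest.raises(ValueError):
            spherical_kmeans(np.empty((0, 3)), 1, seed=0)
        with pytest.raises(ValueError):
            spherical_kmeans(2.0 * P, 2, seed=0)  # not unit length

    def test_agreement_with_sklearn_partition(self, rng):
        """Independent cross-check: on tight separated bundles, Euclidean
        k-means (scikit-learn) and spherical k-means recover the same partition."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        centers = np.eye(4)[:3]
        P = _bundles(rng, centers, per_bundle=6, spread=0.04)
        C = spherical_kmeans(P, 3, seed=0)
        ours = np.argmax(P @ C.T, axis=1)
        km = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=0).fit(P)
        # compare as partitions (labels are arbitrary)
        for lbl in range(3):
            ours_group = ours[km.labels_ == lbl]
            assert len(set(ours_group)) == 1


class TestFitAndResponse:
    def test_single_vector_set_stores_it(self):
        v = np.array([0.0, 1.0, 0.0])
        gs = fit_gnostic_set(v[None, :], "cat", "ch")
        np.testing.assert_allclose(gs.units, v[None, :], atol=1e-12)

    def test_duplicated_training_set_keeps_centroids(self, rng):
        centers = np.eye(3)[:2]
        P = _bundles(rng, centers, per_bundle=10, spread=0.03)
        C1 = spherical_kmeans(P, 2, seed=5)
        C2 = spherical_kmeans(np.vstack([P, P]), 2, seed=11)
        # same global optimum; compare as unordered centroid sets
        d = 1 - (C1 @ C2.T)
        assert d.min(axis=1).max() < 1e-6

    def test_allocation_recomputed_from_n_and_d(self, rng):
        P = unit_rows(rng.standard_normal((50, 8)))
        gs = fit_gnostic_set(P, "c", "ch", AllocationPolicy(alpha=2.0), seed=0)
        assert gs.n_units == allocate_units(50, 8, AllocationPolicy(alpha=2.0))

    def test_singleton_pooling_and_perfect_match(self, rng):
        u = unit_rows(rng.standard_normal((1, 4)))
        gs = GnosticSet("c", "ch", u)
        x = unit_rows(rng.standard_normal((1, 4)))[0]
        assert set_response(gs, x) == pytest.approx(float(u[0] @ x))
        assert set_response(gs, u[0]) == pytest.approx(1.0, abs=1e-12)

    def test_max_pool_idempotent_and_permutation_invariant(self, rng):
        U = unit_rows(rng.standard_normal((5, 4)))
        x = unit_rows(rng.standard_normal((1, 4)))[0]
        gs = GnosticSet("c", "ch", U)
        r = set_response(gs, x)
        best = U[np.argmax(U @ x)]
        assert set_response(gs, x) == set_response(GnosticSet("c", "ch", np.vstack([U, best])), x)
        perm = rng.permutation(5)
        assert set_response(GnosticSet("c", "ch", U[perm]), x) == r
        assert -1.0 <= r <= 1.0

    def test_adding_units_never_decreases_response(self, rng):
        U = unit_rows(rng.standard_normal((3, 4)))
        extra = unit_rows(rng.standard_normal((2, 4)))
        x = unit_rows(rng.standard_normal((1, 4)))[0]
        r0 = set_response(GnosticSet("c", "ch", U), x)
        r1 = set_response(GnosticSet("c", "ch", np.vstack([U, extra])), x)
        assert r1 >= r0

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError):
            GnosticSet("c", "ch", np.array([[2.0, 0.0]]))

    def test_dimension_mismatch_rejected(self, rng):
        gs = GnosticSet("c", "ch", unit_rows(rng.standard_normal((2, 3))))
        with pytest.raises(ValueError):
            set_response(gs, np.ones(4))
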