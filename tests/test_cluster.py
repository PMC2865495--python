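"""Unit and property tests for k-means / k-modes clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clustab as ct
from conftest import brute_kmeans_objective, brute_kmodes_objective


def cmat(rows):
    return ct.DataMatrix(np.asarray(rows, dtype=float))


def gmat(rows):
    return ct.DataMatrix(np.asarray(rows, dtype=np.int64), kind=ct.GENOTYPE)


ONE_D = cmat([[0.0], [1.0], [9.0], [10.0]])


class TestInitCentroids:
    def test_k_equals_distinct_rows_returns_all(self, rng):
        c = ct.init_centroids(ONE_D, 4, rng)
        assert sorted(c.ravel().tolist()) == [0.0, 1.0, 9.0, 10.0]

    def test_k_one_returns_a_row(self, rng):
        c = ct.init_centroids(ONE_D, 1, rng)
        assert c.shape == (1, 1) and c[0, 0] in {0.0, 1.0, 9.0, 10.0}

    def test_same_seed_is_reproducible(self):
        a = ct.init_centroids(ONE_D, 2, np.random.default_rng(7))
        b = ct.init_centroids(ONE_D, 2, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_k_beyond_distinct_rows_raises(self, rng):
        X = cmat([[1.0], [1.0], [2.0]])  # 2 distinct rows
        with pytest.raises(ct.DegenerateInputError):
            ct.init_centroids(X, 3, rng)


class TestAssign:
    def test_point_on_centroid_gets_its_label(self):
        C = np.array([[5.0, 5.0], [0.0, 0.0]])
        X = cmat([[0.0, 0.0], [5.0, 5.0]])
        assert ct.assign_to_nearest(X, C).tolist() == [1, 0]

    def test_one_dimensional_forced_assignment(self):
        labels = ct.assign_to_nearest(ONE_D, np.array([[0.5], [9.5]]))
        assert labels.tolist() == [0, 0, 1, 1]

    def test_tie_breaks_to_lowest_centroid_index(self):
        X = cmat([[1.0]])
        labels = ct.assign_to_nearest(X, np.array([[0.0], [2.0]]))
        assert labels.tolist() == [0]

    def test_workers_do_not_change_labels(self, rng):
        X = ct.DataMatrix(rng.standard_normal((50, 3)))
        C = rng.standard_normal((4, 3))
        serial = ct.assign_to_nearest(X, C, workers=1)
        assert np.array_equal(serial, ct.assign_to_nearest(X, C, workers=4))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ct.MatrixError):
            ct.assign_to_nearest(ONE_D, np.zeros((2, 3)))


class TestMeanUpdate:
    def test_singleton_and_pair_and_global(self):
        X = cmat([[0.0], [1.0], [7.0]])
        c = ct.update_centroids_mean(X, np.array([0, 0, 1]), 2)
        assert c[0, 0] == 0.5 and c[1, 0] == 7.0
        c1 = ct.update_centroids_mean(X, np.zeros(3, dtype=int), 1)
        assert c1[0, 0] == pytest.approx(8.0 / 3.0)

    def test_empty_cluster_reseats_farthest_point(self):
        X = cmat([[0.0], [1.0], [100.0]])
        c = ct.update_centroids_mean(X, np.array([0, 0, 0]), 2)
        # cluster 1 is empty -> seated at the point farthest from its mean
        assert c[1, 0] == 100.0


class TestQuantizationError:
    def test_points_on_centroids_give_zero(self):
        sse, mse = ct.quantization_error(
            ONE_D, np.array([0, 1, 2, 3]), ONE_D.values.copy()
        )
        assert sse == 0.0 and mse == 0.0

    def test_hand_arithmetic(self):
        X = cmat([[0.0], [1.0]])
        sse, mse = ct.quantization_error(
            X, np.array([0, 0]), np.array([[0.5]])
        )
        assert sse == pytest.approx(0.5) and mse == pytest.approx(0.25)

    def test_duplicate_of_centroid_row_leaves_sse_unchanged(self):
        X = cmat([[0.0], [1.0]])
        sse, _ = ct.quantization_error(X, np.array([0, 0]), np.array([[0.5]]))
        X2 = cmat([[0.0], [1.0], [0.5]])
        sse2, _ = ct.quantization_error(
            X2, np.array([0, 0, 0]), np.array([[0.5]])
        )
        assert sse2 == pytest.approx(sse)


class TestKmeans:
    def test_two_well_separated_pairs(self):
        res = ct.kmeans(ONE_D, ct.ClusterConfig(k=2, restarts=10, seed=0))
        assert res.sse == pytest.approx(1.0)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]
        assert sorted(res.centroids.ravel().tolist()) == [0.5, 9.5]
        assert res.sse == pytest.approx(brute_kmeans_objective(ONE_D.values, 2))

    def test_k_one_gives_global_mean_quickly(self):
        res = ct.kmeans(ONE_D, ct.ClusterConfig(k=1, restarts=1, seed=0))
        assert res.centroids[0, 0] == pytest.approx(5.0)
        assert res.converged and res.iterations <= 2

    def test_workers_bitwise_identical(self, rng):
        X = ct.DataMatrix(rng.standard_normal((300, 6)))
        base = ct.kmeans(X, ct.ClusterConfig(k=4, restarts=3, seed=11))
        for w in (2, 8):
            r = ct.kmeans(
                X, ct.ClusterConfig(k=4, restarts=3, seed=11, workers=w)
            )
            assert np.array_equal(r.labels, base.labels)
            assert np.array_equal(r.centroids, base.centroids)
            assert r.sse == base.sse

    def test_objective_non_increasing_over_iterations(self, rng):
        X = ct.DataMatrix(rng.standard_normal((80, 4)))
        C = ct.init_centroids(X, 3, rng)
        labels = ct.assign_to_nearest(X, C)
        objs = []
        for _ in range(15):
            C = ct.update_centroids_mean(X, labels, 3)
            objs.append(ct.quantization_error(X, labels, C)[0])
            new = ct.assign_to_nearest(X, C)
            if np.array_equal(new, labels):
                break
            labels = new
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_no_empty_clusters_in_result(self, rng):
        for _ in range(5):
            X = ct.DataMatrix(rng.standard_normal((12, 2)))
            res = ct.kmeans(X, ct.ClusterConfig(k=3, restarts=5, seed=5))
            assert np.bincount(res.labels, minlength=3).min() > 0

    def test_non_finite_values_rejected_at_load(self):
        with pytest.raises(ct.MatrixError):
            ct.DataMatrix(np.array([[0.0], [np.nan]]))

    def test_restart_prefix_property(self, rng):
        X = ct.DataMatrix(rng.standard_normal((40, 3)))
        sses = [
            ct.kmeans(X, ct.ClusterConfig(k=3, restarts=r, seed=2)).sse
            for r in (1, 3, 6, 10)
        ]
        assert all(b <= a for a, b in zip(sses, sses[1:]))


GENOTYPE_BY_CODE = {0: "AA", 1: "AT", 2: "TT"}


def shared_allele_distance(gx, gy):
    """Oracle: 2 minus the number of shared alleles of two genotype
    strings, counting with multiplicity."""
    from collections import Counter

    cx, cy = Counter(gx), Counter(gy)
    shared = sum(min(cx[a], cy[a]) for a in set(cx) | set(cy))
    return 2 - shared


class TestASD:
    def test_identity(self):
        assert ct.asd([0, 1, 2], [0, 1, 2]) == 0

    @pytest.mark.parametrize("x,y", [(a, b) for a in range(3) for b in range(3)])
    def test_per_locus_matches_shared_allele_count(self, x, y):
        oracle = shared_allele_distance(
            GENOTYPE_BY_CODE[x], GENOTYPE_BY_CODE[y]
        )
        assert ct.asd([x], [y]) == oracle

    def test_sums_over_loci(self):
        assert ct.asd([0, 1, 2], [2, 1, 0]) == 4

    def test_out_of_range_rejected(self):
        with pytest.raises(ct.MatrixError):
            ct.asd([3], [0])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)),
            min_size=1, max_size=20,
        )
    )
    def test_metric_axioms(self, loci):
        x, y, z = (np.array(t) for t in zip(*loci))
        assert ct.asd(x, y) == ct.asd(y, x)
        assert (ct.asd(x, y) == 0) == np.array_equal(x, y)
        assert ct.asd(x, z) <= ct.asd(x, y) + ct.asd(y, z)


class TestModeUpdate:
    def test_identical_rows_give_that_row(self):
        G = gmat([[0, 1, 2], [0, 1, 2]])
        c = ct.update_centroids_mode(G, np.array([0, 0]), 1)
        assert c.tolist() == [[0, 1, 2]]

    def test_majority_and_tie_to_smallest_code(self):
        G = gmat([[0], [0], [1]])
        assert ct.update_centroids_mode(G, np.zeros(3, int), 1).tolist() == [[0]]
        G2 = gmat([[0], [1]])
        assert ct.update_centroids_mode(G2, np.zeros(2, int), 1).tolist() == [[0]]


class TestKmodes:
    def test_duplicated_groups_separate_perfectly(self):
        G = gmat([[0, 0, 0]] * 3 + [[2, 2, 2]] * 3)
        res = ct.kmodes(G, ct.ClusterConfig(k=2, restarts=5, seed=0))
        assert res.sse == 0.0
        assert len(set(res.labels[:3])) == 1 != len(set(res.labels.tolist()))

    def test_matches_exhaustive_partition_search(self, rng):
        G = gmat(rng.integers(0, 3, size=(6, 4)))
        res = ct.kmodes(G, ct.ClusterConfig(k=2, restarts=20, seed=1))
        assert res.sse == pytest.approx(brute_kmodes_objective(G.values, 2))

    def test_k_one_gives_columnwise_modes(self, rng):
        G = gmat(rng.integers(0, 3, size=(9, 5)))
        res = ct.kmodes(G, ct.ClusterConfig(k=1, restarts=1, seed=0))
        expected = [
            int(np.bincount(G.values[:, j], minlength=3).argmax())
            for j in range(5)
        ]
        assert res.centroids.tolist() == [expected]

    def test_workers_bitwise_identical(self, rng):
        G = gmat(rng.integers(0, 3, size=(200, 12)))
        base = ct.kmodes(G, ct.ClusterConfig(k=3, restarts=3, seed=9))
        r = ct.kmodes(
            G, ct.ClusterConfig(k=3, restarts=3, seed=9, workers=4)
        )
        assert np.array_equal(r.labels, base.labels)
        assert np.array_equal(r.centroids, base.centroids)
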