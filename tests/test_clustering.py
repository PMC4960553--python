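"""Batch-SOM training, BMU search and second-level K-means++ clustering."""

import numpy as np
import pytest

from mrci.clustering import (
    SOMConfig,
    bmu,
    bmus,
    component_planes,
    init_som,
    kmeanspp_cluster,
    quantization_error,
    train_blsom,
)
from mrci.errors import ClusteringError, DimensionMismatchError, EmptyInputError

from conftest import exhaustive_min_sse, feature_matrix, flat_codebook


class TestInitSom:
    def test_planar_features_give_planar_weights(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 4))
        coeff = rng.normal(size=(100, 2))
        X = 3.0 + coeff @ basis  # features on a 2D affine plane
        cb = init_som(feature_matrix(X), SOMConfig(grid_rows=5, grid_cols=5))
        centered = cb.weights - X.mean(axis=0)
        # residual after projecting onto the plane's span must vanish
        q, _ = np.linalg.qr(basis.T)
        resid = centered - (centered @ q) @ q.T
        assert np.abs(resid).max() < 1e-8

    def test_duplicated_rows_identical_init(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        cfg = SOMConfig(grid_rows=4, grid_cols=4)
        cb1 = init_som(feature_matrix(X), cfg)
        cb2 = init_som(feature_matrix(np.vstack([X, X])), cfg)
        np.testing.assert_allclose(cb1.weights, cb2.weights, atol=1e-9)

    def test_single_unit_is_feature_mean(self):
        X = np.random.default_rng(2).normal(size=(30, 4))
        cb = init_som(feature_matrix(X), SOMConfig(grid_rows=1, grid_cols=1))
        np.testing.assert_allclose(cb.weights[0], X.mean(axis=0), atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(EmptyInputError):
            init_som(feature_matrix(np.zeros((1, 4))), SOMConfig())


class TestTrainBlsom:
    def test_single_unit_converges_to_mean(self):
        X = np.random.default_rng(3).normal(size=(40, 4))
        cfg = SOMConfig(grid_rows=1, grid_cols=1, epochs=3,
                        initial_radius=1.0, final_radius=1.0)
        cb = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        np.testing.assert_allclose(cb.weights[0], X.mean(axis=0), atol=1e-12)

    def test_row_permutation_bit_identical(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 4))
        cfg = SOMConfig(grid_rows=5, grid_cols=5, epochs=8,
                        initial_radius=3.0, final_radius=0.5)
        cb1 = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        Xp = X[rng.permutation(len(X))]
        cb2 = train_blsom(init_som(feature_matrix(Xp), cfg), feature_matrix(Xp), cfg)
        assert np.array_equal(cb1.weights, cb2.weights)
        assert cb1.quantization_error_trace == cb2.quantization_error_trace

    def test_two_unit_map_splits_separated_data(self):
        # 1-D data {0, 0, 10, 10}: with a vanishing kernel the batch update's
        # fixed point puts one unit on each value
        X = np.array([[0.0] * 4, [0.0] * 4, [10.0] * 4, [10.0] * 4])
        cfg = SOMConfig(grid_rows=2, grid_cols=1, epochs=30,
                        initial_radius=1.0, final_radius=0.05)
        cb = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        got = sorted(cb.weights[:, 0].round(6).tolist())
        assert got == [0.0, 10.0]

    @pytest.mark.parametrize("seed", range(20))
    def test_squared_error_non_increasing_at_fixed_radius(self, seed):
        # at a fixed radius in the quantization regime (kernel numerically a
        # point mass) the batch epoch is a Lloyd step, whose objective — the
        # mean squared sample-to-BMU distance — can never increase
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(60, 200), 4))
        cfg = SOMConfig(grid_rows=4, grid_cols=4, epochs=12,
                        initial_radius=0.25, final_radius=0.25)
        cb = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        trace = np.array(cb.squared_error_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_hit_counts_sum_to_samples(self):
        X = np.random.default_rng(5).normal(size=(120, 4))
        cfg = SOMConfig(grid_rows=4, grid_cols=4, epochs=5,
                        initial_radius=2.0, final_radius=0.5)
        cb = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        assert cb.hit_counts.sum() == 120

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(6).normal(size=(50, 4))
        cfg = SOMConfig(grid_rows=3, grid_cols=3, epochs=2)
        cb = init_som(feature_matrix(X), cfg)
        with pytest.raises(DimensionMismatchError):
            train_blsom(cb, np.zeros((10, 3)), cfg)


class TestBmu:
    def test_nearest_unit(self):
        cb = flat_codebook(np.array([[0.0] * 4, [1.0] * 4]))
        assert bmu(cb, np.array([0.9] * 4)) == 1

    def test_tie_breaks_to_lowest_index(self):
        cb = flat_codebook(np.array([[0.0] * 4, [1.0] * 4]))
        assert bmu(cb, np.array([0.5] * 4)) == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cb = flat_codebook(rng.normal(size=(rng.integers(5, 400), 4)))
            X = rng.normal(size=(20, 4))
            got = bmus(cb, X)
            expected = np.array([
                int(np.argmin(((cb.weights - x) ** 2).sum(axis=1))) for x in X
            ])
            np.testing.assert_array_equal(got, expected)


class TestQuantizationError:
    def test_zero_when_features_equal_units(self):
        W = np.random.default_rng(8).normal(size=(10, 4))
        assert quantization_error(flat_codebook(W), W) == 0.0

    def test_single_unit_at_mean(self):
        cb = flat_codebook(np.zeros((1, 4)))
        X = np.array([[-1.0, 0, 0, 0], [1.0, 0, 0, 0]])
        assert quantization_error(cb, X) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cb = flat_codebook(rng.normal(size=(30, 4)))
            X = rng.normal(size=(40, 4))
            expected = np.mean([
                np.sqrt(((cb.weights - x) ** 2).sum(axis=1)).min() for x in X
            ])
            assert abs(quantization_error(cb, X) - expected) < 1e-12


class TestKmeansPP:
    def test_square_corners_matches_exhaustive_bipartition(self):
        X = np.array([[0, 0, 0, 0], [0, 1, 0, 0], [5, 0, 0, 0], [5, 1, 0, 0]], float)
        lab = kmeanspp_cluster(flat_codebook(X), K=2, seed=0, n_restarts=10)
        assert abs(lab.inertia - exhaustive_min_sse(X, 2)) < 1e-9
        assert lab.unit_class[0] == lab.unit_class[1] != lab.unit_class[2]

    def test_k_equals_distinct_units_zero_inertia(self):
        X = np.arange(8.0).reshape(-1, 1).repeat(4, axis=1)
        lab = kmeanspp_cluster(flat_codebook(X), K=8, seed=0)
        assert lab.inertia == 0.0
        assert sorted(lab.unit_class) == list(range(1, 9))

    def test_two_value_line(self):
        X = np.array([[0.0] * 4, [0.0] * 4, [10.0] * 4, [10.0] * 4])
        lab = kmeanspp_cluster(flat_codebook(X), K=2, seed=1)
        assert lab.inertia == 0.0
        # descending center mean: the 10s become class 1
        np.testing.assert_array_equal(lab.unit_class, [2, 2, 1, 1])

    @pytest.mark.parametrize("seed", range(25))
    def test_attains_brute_force_optimum_when_separated(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        n = int(rng.integers(K + 2, 13))
        centers = rng.normal(size=(K, 4))
        dmin = min(
            np.linalg.norm(centers[i] - centers[j])
            for i in range(K) for j in range(i + 1, K)
        )
        centers *= 8.0 / max(dmin, 1e-9)  # separation >= 4x within-spread
        X = centers[rng.integers(0, K, n)] + rng.normal(size=(n, 4)) * 0.5
        lab = kmeanspp_cluster(flat_codebook(X), K=K, seed=seed, n_restarts=25)
        assert abs(lab.inertia - exhaustive_min_sse(X, K)) <= 1e-6 * max(1, lab.inertia)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(10).normal(size=(40, 4))
        cb = flat_codebook(X)
        lab1 = kmeanspp_cluster(cb, K=5, seed=3)
        lab2 = kmeanspp_cluster(cb, K=5, seed=3)
        np.testing.assert_array_equal(lab1.unit_class, lab2.unit_class)
        assert lab1.inertia == lab2.inertia

    def test_every_class_non_empty(self):
        X = np.random.default_rng(11).normal(size=(50, 4))
        lab = kmeanspp_cluster(flat_codebook(X), K=7, seed=0)
        assert set(lab.unit_class) == set(range(1, 8))

    def test_k_larger_than_distinct_units_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ClusteringError):
            kmeanspp_cluster(flat_codebook(X), K=2, seed=0)


class TestComponentPlanes:
    def _trained(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 4))
        cfg = SOMConfig(grid_rows=4, grid_cols=5, epochs=5,
                        initial_radius=2.0, final_radius=0.5)
        cb = train_blsom(init_som(feature_matrix(X), cfg), feature_matrix(X), cfg)
        return cb, kmeanspp_cluster(cb, K=3, seed=0)

    def test_planes_are_codebook_columns(self):
        cb, lab = self._trained()
        planes, _ = component_planes(cb, lab, ("t1", "t1ce", "t2", "flair"))
        for j, name in enumerate(("t1", "t1ce", "t2", "flair")):
            np.testing.assert_array_equal(planes[name].ravel(), cb.weights[:, j])

    def test_single_class_no_borders(self):
        cb, lab = self._trained()
        lab.unit_class = np.ones_like(lab.unit_class)
        _, borders = component_planes(cb, lab)
        assert borders == []

    def test_borders_exactly_where_classes_differ(self):
        cb, lab = self._trained()
        _, borders = component_planes(cb, lab)
        grid = lab.unit_class.reshape(cb.grid_rows, cb.grid_cols)
        expected = 0
        for r in range(cb.grid_rows):
            for c in range(cb.grid_cols):
                if c + 1 < cb.grid_cols and grid[r, c] != grid[r, c + 1]:
                    expected += 1
                if r + 1 < cb.grid_rows and grid[r, c] != grid[r + 1, c]:
                    expected += 1
        assert len(borders) == expected
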