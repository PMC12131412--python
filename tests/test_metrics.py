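import numpy as np
import pytest
import scipy.sparse as sp

import stloc
from stloc.errors import UndefinedStatisticError, ValidationError


def dense_morans_oracle(x, w_dense):
    """Brute-force double loop over the Moran's I definition."""
    n = len(x)
    xb = x.mean()
    num = sum(
        w_dense[i, j] * (x[i] - xb) * (x[j] - xb) for i in range(n) for j in range(n)
    )
    return n / w_dense.sum() * num / sum((xi - xb) ** 2 for xi in x)


class TestSpatialWeights:
    def test_inverse_distance_hand_value(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0]])
        w = stloc.build_spatial_weights(pts, mode="inverse-distance", threshold=10.0)
        assert w.pairs[0, 1] == w.pairs[1, 0] == pytest.approx(25.0)  # 100/4
        assert w.total == pytest.approx(50.0)

    def test_beyond_threshold_gives_zero_weights(self):
        pts = np.array([[0.0, 0.0], [11.0, 0.0]])
        w = stloc.build_spatial_weights(pts, mode="inverse-distance", threshold=10.0)
        assert w.total == 0.0
        with pytest.raises(UndefinedStatisticError):
            stloc.morans_i(np.array([1.0, 2.0]), w)

    def test_duplicate_points_rejected_in_inverse_mode(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 0.0]])
        with pytest.raises(ValidationError, match="duplicate"):
            stloc.build_spatial_weights(pts, mode="inverse-distance", threshold=5.0)

    def test_knn_union_on_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        w = stloc.build_spatial_weights(pts, mode="knn", k=1)
        # middle point is the nearest neighbor of both ends -> symmetric union
        assert w.pairs[0, 1] == w.pairs[1, 0] == 1
        assert w.pairs[2, 1] == w.pairs[1, 2] == 1
        assert w.pairs[0, 2] == 0
        assert np.all(w.pairs.diagonal() == 0)


class TestMoransI:
    def test_two_point_anticorrelation(self):
        w = stloc.SpatialWeights(
            mode="custom", pairs=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        )
        assert stloc.morans_i(np.array([-1.0, 1.0]), w) == pytest.approx(-1.0)
        assert stloc.bivariate_morans_i(
            np.array([-1.0, 1.0]), np.array([1.0, -1.0]), w
        ) == pytest.approx(1.0)

    def test_shift_and_scale_invariance(self, rng):
        pts = rng.uniform(0, 10, size=(15, 2))
        w = stloc.build_spatial_weights(pts, mode="knn", k=3)
        x = rng.normal(size=15)
        base = stloc.morans_i(x, w)
        assert stloc.morans_i(x + 7.3, w) == pytest.approx(base, abs=1e-12)
        assert stloc.morans_i(2.9 * x, w) == pytest.approx(base, abs=1e-12)

    def test_matches_dense_double_loop_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(5, 30)
            pts = rng.uniform(0, 50, size=(n, 2))
            x = rng.normal(size=n)
            w = stloc.build_spatial_weights(
                pts, mode="inverse-distance", threshold=25.0
            )
            if w.total == 0:
                continue
            assert stloc.morans_i(x, w) == pytest.approx(
                dense_morans_oracle(x, w.pairs.toarray()), abs=1e-12
            )

    def test_matches_scanpy_implementation(self, rng):
        """Independent cross-check against the single-cell ecosystem's
        Moran's I on an identical weight graph."""
        import scanpy as sc

        pts = rng.uniform(0, 100, size=(40, 2))
        x = rng.gamma(2, 1, size=40)
        w = stloc.build_spatial_weights(pts, mode="knn", k=6)
        ours = stloc.morans_i(x, w)
        theirs = float(sc.metrics.morans_i(w.pairs, x[None, :])[0])
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_constant_vector_raises(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        w = stloc.build_spatial_weights(pts, mode="knn", k=1)
        with pytest.raises(UndefinedStatisticError):
            stloc.morans_i(np.ones(2), w)

    def test_bvi_reduces_to_morans_when_y_equals_x(self, rng):
        pts = rng.uniform(0, 20, size=(25, 2))
        w = stloc.build_spatial_weights(pts, mode="inverse-distance", threshold=10.0)
        x = rng.normal(size=25)
        assert stloc.bivariate_morans_i(x, x, w) == pytest.approx(
            stloc.morans_i(x, w), abs=1e-12
        )

    def test_bvi_affine_invariance_in_second_argument(self, rng):
        pts = rng.uniform(0, 20, size=(20, 2))
        w = stloc.build_spatial_weights(pts, mode="knn", k=4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = stloc.bivariate_morans_i(x, y, w)
        assert stloc.bivariate_morans_i(x, 3.0 * y + 5.0, w) == pytest.approx(
            base, abs=1e-12
        )


class TestPairwiseMetrics:
    def test_pair_counts_and_unit_square(self):
        assert len(stloc.pairwise_distances(np.zeros((2, 2)) + [[0, 0], [1, 1]])) == 1
        square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        d = np.sort(stloc.pairwise_distances(square))
        np.testing.assert_allclose(d, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])

    def test_perfect_prediction(self, rng):
        pts = rng.uniform(0, 1, size=(12, 2))
        assert stloc.pairwise_pearson_r(pts, pts.copy()) == pytest.approx(1.0)
        assert stloc.pairwise_rmse(pts, pts.copy()) == 0.0

    @pytest.mark.parametrize("angle", [0.3, np.pi / 4, 2.0])
    def test_rigid_transform_invariance(self, rng, angle):
        """Rotation + reflection + translation of predictions leaves
        pairwise r at 1 and pairwise RMSE at 0."""
        pts = rng.uniform(0, 1, size=(20, 2))
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        F = np.array([[1.0, 0.0], [0.0, -1.0]])  # reflection
        moved = pts @ R.T @ F + np.array([3.0, -2.0])
        assert stloc.pairwise_pearson_r(pts, moved) == pytest.approx(1.0, abs=1e-12)
        assert stloc.pairwise_rmse(pts, moved) == pytest.approx(0.0, abs=1e-12)

    def test_collapsed_prediction(self, rng):
        pts = rng.uniform(0, 1, size=(8, 2))
        collapsed = np.tile(pts[0], (8, 1))
        d_true = stloc.pairwise_distances(pts)
        assert stloc.pairwise_rmse(pts, collapsed) == pytest.approx(
            np.sqrt(np.mean(d_true**2))
        )
        with pytest.raises(UndefinedStatisticError):
            stloc.pairwise_pearson_r(pts, collapsed)


@pytest.fixture(scope="module")
def cv_setup():
    rng = np.random.default_rng(8)
    n = 120
    coords = rng.uniform(0, 100, size=(n, 2))
    expr = rng.gamma(2, 1, size=(n, 8))
    expr[:, 0] = coords[:, 0] / 10
    expr[:, 1] = coords[:, 1] / 10
    ds = stloc.SpatialDataset(
        expr=expr,
        gene_ids=[f"g{i}" for i in range(8)],
        obs_ids=[f"s{i}" for i in range(n)],
        coords=coords,
    )
    spec = stloc.ModelSpec(n_genes=8, hidden_widths=(8,), l1_lambda=0.0)
    cfg = stloc.TrainConfig(batch_size=32, max_epochs=25, seed=0)
    return ds, spec, cfg


class TestCrossvalidate:
    def test_partition_covers_everything_once_and_is_seeded(self, cv_setup):
        ds, spec, cfg = cv_setup
        a = stloc.crossvalidate(ds, spec, cfg, n_folds=4, seed=3)
        b = stloc.crossvalidate(ds, spec, cfg, n_folds=4, seed=3)
        counts = np.bincount(a.fold_assignment, minlength=4)
        assert counts.sum() == ds.n_obs and (counts > 0).all()
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.pooled_pred, b.pooled_pred)

    def test_beats_label_permuted_baseline(self, cv_setup):
        ds, spec, cfg = cv_setup
        result = stloc.crossvalidate(ds, spec, cfg, n_folds=4, seed=3)
        permuted = ds.copy()
        permuted.coords = permuted.coords[np.random.default_rng(1).permutation(ds.n_obs)]
        baseline = stloc.crossvalidate(permuted, spec, cfg, n_folds=4, seed=3)
        assert result.mean_r > baseline.mean_r

    def test_bootstrap_mean_near_point_estimate(self, cv_setup):
        ds, spec, cfg = cv_setup
        result = stloc.crossvalidate(
            ds, spec, cfg, n_folds=4, seed=3, bootstrap_reps=200
        )
        bs = result.bootstrap
        assert bs["reps"] == 200
        assert abs(bs["rmse_mean"] - result.pooled_rmse) < 5 * bs["rmse_sd"] + 0.05

    def test_too_small_folds_rejected(self, cv_setup):
        ds, spec, cfg = cv_setup
        with pytest.raises(ValidationError):
            stloc.crossvalidate(ds.subset_obs(range(8)), spec, cfg, n_folds=4, seed=0)
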