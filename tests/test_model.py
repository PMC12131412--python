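import numpy as np
import pytest

import stloc
from stloc.errors import ValidationError
from stloc.model import loss_and_grads

# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------


class TestBuildModel:
    def test_shape_chain(self):
        spec = stloc.ModelSpec(n_genes=3, hidden_widths=(4,), out_dim=2)
        m = stloc.build_model(spec, seed=0)
        assert [w.shape for w in m.weights] == [(3, 4), (4, 2)]
        assert all(not b.any() for b in m.biases)

    def test_same_seed_identical_weights(self):
        spec = stloc.ModelSpec(n_genes=5, hidden_widths=(8, 4))
        a = stloc.build_model(spec, seed=9)
        b = stloc.build_model(spec, seed=9)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_no_hidden_layers_degenerates_to_linear_sigmoid(self):
        spec = stloc.ModelSpec(n_genes=6, hidden_widths=(), out_dim=2)
        m = stloc.build_model(spec, seed=0)
        assert [w.shape for w in m.weights] == [(6, 2)]
        out = stloc.predict(m, np.zeros((1, 6)))
        np.testing.assert_allclose(out, 0.5)  # sigmoid of zero bias

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValidationError):
            stloc.ModelSpec(n_genes=3, hidden_widths=(4, 0))


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------


class TestLosses:
    def test_rmse_hand_values(self):
        assert stloc.rmse(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0
        assert stloc.rmse(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == 5.0

    def test_rmse_homogeneity(self, rng):
        y = rng.normal(size=(10, 2))
        e = rng.normal(size=(10, 2))
        assert stloc.rmse(y, y + 3 * e) == pytest.approx(3 * stloc.rmse(y, y + e))

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValidationError):
            stloc.rmse(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_total_loss_reduces_to_rmse_at_zero_lambda(self, rng):
        y, yh = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        w = [rng.normal(size=(4, 2))]
        assert stloc.total_loss(y, yh, w, 0.0) == stloc.rmse(y, yh)

    def test_total_loss_hand_value_and_linearity(self):
        y = np.array([[0.2, 0.8]])
        w = [np.array([[2.0], [-3.0]])]
        assert stloc.total_loss(y, y, w, 0.1) == pytest.approx(0.5)
        assert stloc.total_loss(y, y, w, 0.2) == pytest.approx(1.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            stloc.total_loss(np.zeros((1, 2)), np.zeros((1, 2)), [], -1.0)


def _finite_difference_check(batch_norm, tol):
    rng = np.random.default_rng(0)
    spec = stloc.ModelSpec(
        n_genes=3, hidden_widths=(4, 2), dropout_rate=0.0, l1_lambda=1e-3,
        batch_norm=batch_norm,
    )
    m = stloc.build_model(spec, seed=5)
    if batch_norm:  # move scale/shift off their init so their grads are generic
        for g in m.bn.gamma:
            g += rng.normal(0, 0.1, g.shape)
        for b in m.bn.beta:
            b += rng.normal(0, 0.1, b.shape)
    X = rng.normal(2, 1, (7, 3))
    Y = rng.uniform(0.2, 0.8, (7, 2))

    def f():
        return loss_and_grads(m.weights, m.biases, X, Y, spec.l1_lambda, bn=m.bn)

    _, grads = f()
    param_sets = [(m.weights, grads["w"]), (m.biases, grads["b"])]
    if batch_norm:
        param_sets += [(m.bn.gamma, grads["gamma"]), (m.bn.beta, grads["beta"])]
    eps = 1e-6
    for mats, gs in param_sets:
        for W, G in zip(mats, gs):
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = W[i]
                W[i] = orig + eps
                lp, _ = f()
                W[i] = orig - eps
                lm, _ = f()
                W[i] = orig
                fd = (lp - lm) / (2 * eps)
                # mixed tolerance: relative where the gradient is large,
                # absolute where it is (near) zero and FD is rounding noise
                assert abs(fd - G[i]) <= tol * (1.0 + abs(fd) + abs(G[i]))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Backprop of the penalized loss vs central differences, 3-gene toy."""
        _finite_difference_check(batch_norm=False, tol=1e-4)

    def test_analytic_matches_finite_differences_with_batchnorm(self):
        _finite_difference_check(batch_norm=True, tol=1e-4)


# --------------------------------------------------------------------------
# Training behavior
# --------------------------------------------------------------------------


def _signal_dataset(n=240, n_noise=20, seed=0):
    """x-coordinate carried by one gene, the rest pure noise."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, size=(n, 2))
    expr = rng.gamma(2.0, 1.0, size=(n, n_noise + 1))
    expr[:, 0] = coords[:, 0] / 10.0
    return stloc.SpatialDataset(
        expr=expr,
        gene_ids=[f"g{i}" for i in range(n_noise + 1)],
        obs_ids=[f"s{i}" for i in range(n)],
        coords=coords,
    )


class TestTrain:
    def test_training_improves_on_learnable_signal(self):
        ds = _signal_dataset()
        norm = stloc.fit_coord_normalizer(ds.coords)
        spec = stloc.ModelSpec(n_genes=21, hidden_widths=(16, 4), l1_lambda=0.0)
        cfg = stloc.TrainConfig(batch_size=48, max_epochs=40, seed=3)
        m0 = stloc.build_model(spec, seed=3)
        y = stloc.normalize_coords(ds.coords, norm)
        before = stloc.rmse(y, stloc.predict(m0, ds.dense_expr()))
        trained = stloc.train(m0, ds, norm, cfg)
        after = stloc.rmse(y, stloc.predict(trained, ds.dense_expr()))
        assert after < before

    def test_seeded_training_is_reproducible(self):
        ds = _signal_dataset(n=120, n_noise=5)
        norm = stloc.fit_coord_normalizer(ds.coords)
        spec = stloc.ModelSpec(n_genes=6, hidden_widths=(8,))
        cfg = stloc.TrainConfig(batch_size=32, max_epochs=10, seed=11)
        runs = [
            stloc.train(stloc.build_model(spec, seed=11), ds, norm, cfg)
            for _ in range(2)
        ]
        assert runs[0].history["loss"] == runs[1].history["loss"]
        for a, b in zip(runs[0].weights, runs[1].weights):
            np.testing.assert_array_equal(a, b)

    def test_large_lambda_shrinks_weight_norm(self):
        ds = _signal_dataset(n=150, n_noise=8)
        norm = stloc.fit_coord_normalizer(ds.coords)
        cfg = stloc.TrainConfig(batch_size=64, max_epochs=25, seed=1)
        norms = {}
        for lam in (0.0, 1e3):
            spec = stloc.ModelSpec(n_genes=9, hidden_widths=(8,), l1_lambda=lam)
            m = stloc.train(stloc.build_model(spec, seed=1), ds, norm, cfg)
            norms[lam] = stloc.l1_penalty(m.weights)
        assert norms[1e3] < norms[0.0]

    def test_oversized_batch_clamped_with_warning(self):
        ds = _signal_dataset(n=60, n_noise=4)
        norm = stloc.fit_coord_normalizer(ds.coords)
        spec = stloc.ModelSpec(n_genes=5, hidden_widths=(4,))
        cfg = stloc.TrainConfig(batch_size=4096, max_epochs=3, seed=0)
        with pytest.warns(UserWarning, match="clamped"):
            stloc.train(stloc.build_model(spec, seed=0), ds, norm, cfg)

    def test_history_recorded_and_rbar_in_range(self, tiny_trained):
        _, _, model, _ = tiny_trained
        assert len(model.history["loss"]) == len(model.history["val_loss"]) > 0
        assert -1.0 <= model.mean_pred_corr <= 1.0


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------


class TestPredict:
    def test_outputs_strictly_inside_unit_interval(self, tiny_trained, rng):
        _, _, model, _ = tiny_trained
        X = rng.gamma(2, 2, size=(10, model.spec.n_genes))
        out = stloc.predict(model, X)
        assert out.shape == (10, 2)
        assert (out > 0).all() and (out < 1).all()

    def test_pointwise_map_duplicates_rows(self, tiny_trained, rng):
        _, _, model, _ = tiny_trained
        x = rng.gamma(2, 2, size=(1, model.spec.n_genes))
        out = stloc.predict(model, np.vstack([x, x]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_gene_order_mismatch_rejected(self, tiny_trained):
        normalized, _, model, _ = tiny_trained
        scrambled = normalized.subset_genes(list(reversed(normalized.gene_ids)))
        with pytest.raises(ValidationError, match="gene"):
            stloc.predict(model, scrambled)

    def test_mc_dropout_is_seeded_and_differs_from_point_mode(self, tiny_trained, rng):
        _, _, model, _ = tiny_trained
        X = rng.gamma(2, 2, size=(5, model.spec.n_genes))
        a = stloc.predict(model, X, mc_dropout=8, seed=4)
        b = stloc.predict(model, X, mc_dropout=8, seed=4)
        np.testing.assert_array_equal(a, b)
        point = stloc.predict(model, X)
        assert not np.array_equal(a, point)


def test_save_load_round_trip(tmp_path, tiny_trained):
    _, normalizer, model, _ = tiny_trained
    path = tmp_path / "model.h5"
    stloc.save_model(model, path, normalizer=normalizer)
    back, norm_back = stloc.load_model(path)
    for a, b in zip(model.weights, back.weights):
        np.testing.assert_array_equal(a, b)
    assert back.gene_ids == model.gene_ids
    assert back.mean_pred_corr == pytest.approx(model.mean_pred_corr)
    np.testing.assert_array_equal(norm_back.mins, normalizer.mins)
    # loaded model predicts identically
    X = np.ones((3, model.spec.n_genes))
    np.testing.assert_array_equal(stloc.predict(model, X), stloc.predict(back, X))
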