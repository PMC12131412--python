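"""Coordinate-regression network: definition, training, prediction.

The regressor is a fully connected network that maps a normalized
log-expression vector to min-max-normalized spatial coordinates.  The
default architecture has 6 hidden layers of widths 4096, 1024, 256, 64,
16, 4 with rectifier activations; the output layer is sigmoid so
predictions live in (0, 1) per axis.  Training minimizes

    loss = RMSE + lambda * sum_i sum_jk |W_ijk|

where RMSE = sqrt( sum_t ||y_t - yhat_t||^2 / N ) over the N observations
of a batch (the squared error sums over coordinate components) and the L1
penalty runs over all dense weight matrices, biases excluded.  The
penalty shrinks weights that do not contribute to location prediction
toward zero, which is what makes the weight-backtracking gene scores
(svg module) informative.

Hidden pre-activations are batch-normalized by default (learned scale and
shift, running statistics at inference).  Without normalization the
narrow tail of the funnel architecture (widths 16 and 4) is prone to
complete rectifier die-off early in training — every unit's
pre-activation drifts negative while the output chases the coordinate
mean, after which gradients vanish and the model is stuck predicting a
constant.  Batch normalization re-centers those pre-activations every
step and removes the failure mode; it can be disabled per spec.

Optimization is mini-batch Adam (lr 0.001, beta1 0.9, beta2 0.999,
eps 1e-7) with dropout (rate 0.05) after activation on the input layer
and the first five hidden layers, learning-rate halving after 20 epochs
without validation-loss improvement down to 1e-5, and early stopping with
patience 50 (best-validation weights restored).  All randomness — the
Glorot-normal initialization, validation split, per-epoch shuffling and
dropout masks — flows from explicit seeds, so training is reproducible
run-to-run in single-threaded mode.

Everything is plain numpy with analytic gradients; the gradients of the
full penalized loss (with or without batch normalization) are exposed for
verification against finite differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .core_data import CoordNormalizer, SpatialDataset, normalize_coords
from .errors import TrainingError, ValidationError

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "BatchNormState",
    "build_model",
    "rmse",
    "l1_penalty",
    "total_loss",
    "loss_and_grads",
    "train",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_DEFAULT_HIDDEN = (4096, 1024, 256, 64, 16, 4)
# dropout covers the input layer and at most this many leading hidden layers
_N_DROPOUT_HIDDEN = 5
_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99


# ---------------------------------------------------------------------------
# Specs and containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Architecture and regularization of the coordinate regressor.

    ``hidden_widths`` may be empty, giving a degenerate linear-sigmoid
    model with a single n_genes x out_dim weight matrix.
    """

    n_genes: int
    out_dim: int = 2
    hidden_widths: tuple[int, ...] = _DEFAULT_HIDDEN
    dropout_rate: float = 0.05
    l1_lambda: float = 1e-8
    batch_norm: bool = True

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.n_genes <= 0 or self.out_dim not in (2, 3):
            raise ValidationError("n_genes must be positive and out_dim in {2, 3}")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValidationError("hidden widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.l1_lambda < 0:
            raise ValidationError("l1_lambda must be non-negative")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_genes, *self.hidden_widths, self.out_dim)


@dataclass
class TrainConfig:
    """Optimization settings.

    ``batch_size`` defaults to 4096; smaller values (16 or 128) suit
    small spot counts — the effective batch is clamped to the training-set
    size with a warning when larger.
    """

    learning_rate: float = 1e-3
    batch_size: int = 4096
    max_epochs: int = 500
    lr_factor: float = 0.5
    lr_patience: int = 20
    min_lr: float = 1e-5
    early_stopping_patience: int = 50
    validation_fraction: float = 0.1
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    restore_best: bool = True

    def __post_init__(self) -> None:
        if self.min_lr > self.learning_rate:
            raise ValidationError("min_lr must not exceed learning_rate")
        if self.lr_patience < 1 or self.early_stopping_patience < 1:
            raise ValidationError("patience values must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValidationError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")


@dataclass
class BatchNormState:
    """Learned scale/shift and running statistics per hidden layer."""

    gamma: list[np.ndarray]
    beta: list[np.ndarray]
    run_mean: list[np.ndarray]
    run_var: list[np.ndarray]

    @classmethod
    def initial(cls, hidden_widths: tuple[int, ...]) -> "BatchNormState":
        return cls(
            gamma=[np.ones(w) for w in hidden_widths],
            beta=[np.zeros(w) for w in hidden_widths],
            run_mean=[np.zeros(w) for w in hidden_widths],
            run_var=[np.ones(w) for w in hidden_widths],
        )

    def copy(self) -> "BatchNormState":
        return BatchNormState(
            gamma=[g.copy() for g in self.gamma],
            beta=[b.copy() for b in self.beta],
            run_mean=[m.copy() for m in self.run_mean],
            run_var=[v.copy() for v in self.run_var],
        )


@dataclass
class TrainedModel:
    """Network parameters plus training provenance.

    ``weights[i]`` has shape (fan_in, fan_out) following the layer-size
    chain of the spec; ``history`` holds per-epoch penalized training and
    validation losses; ``mean_pred_corr`` is the mean over coordinate axes
    of the Pearson correlation between predicted and reference normalized
    coordinates on the validation split (the r-bar entering the
    normalized gene-importance scores).
    """

    spec: ModelSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn: BatchNormState | None = None
    gene_ids: list[str] | None = None
    history: dict = field(default_factory=dict)
    mean_pred_corr: float | None = None

    def __post_init__(self) -> None:
        sizes = self.spec.layer_sizes
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValidationError("weight/bias count does not match spec chain")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise ValidationError(
                    f"layer {i}: expected W {(sizes[i], sizes[i + 1])}, got {w.shape}"
                )
        if self.spec.batch_norm and self.bn is None:
            self.bn = BatchNormState.initial(self.spec.hidden_widths)


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Initialize an untrained model: Glorot-normal weights, zero biases."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        std = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    bn = BatchNormState.initial(spec.hidden_widths) if spec.batch_norm else None
    return TrainedModel(spec=spec, weights=weights, biases=biases, bn=bn)


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """sqrt( sum_t ||y_t - yhat_t||^2 / N ), N = number of rows."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.ndim != 2 or y.shape[0] < 1:
        raise ValidationError("expected (N>=1, d) coordinate matrices")
    return float(np.sqrt(np.sum((y - y_hat) ** 2) / y.shape[0]))


def l1_penalty(weights: list[np.ndarray]) -> float:
    """Sum of absolute values over all weight matrices (biases excluded)."""
    return float(sum(np.abs(w).sum() for w in weights))


def total_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    weights: list[np.ndarray],
    l1_lambda: float,
) -> float:
    """Penalized loss: rmse + lambda * sum |W|."""
    if l1_lambda < 0:
        raise ValidationError("l1_lambda must be non-negative")
    return rmse(y, y_hat) + l1_lambda * l1_penalty(weights)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    X: np.ndarray,
    dropout_masks: list[np.ndarray | None] | None = None,
    bn: BatchNormState | None = None,
    bn_batch_stats: bool = False,
):
    """Propagate X through the network.

    ``dropout_masks`` is a list of length n_layers (input activation plus
    each hidden activation); entries are pre-scaled inverted-dropout masks
    or None.  With ``bn`` given, hidden pre-activations are normalized
    using per-batch statistics (training mode, ``bn_batch_stats=True``) or
    the stored running statistics (inference).  Returns
    (activations, caches, y_hat): ``activations[i]`` is the (possibly
    dropped) input to weight matrix i; ``caches[i]`` holds the
    intermediates of hidden layer i needed by backprop.
    """
    n_mats = len(weights)
    a = X
    if dropout_masks is not None and dropout_masks[0] is not None:
        a = a * dropout_masks[0]
    activations = [a]
    caches = []
    for i in range(n_mats - 1):  # hidden layers
        z = a @ weights[i] + biases[i]
        if bn is not None:
            if bn_batch_stats:
                mu, var = z.mean(axis=0), z.var(axis=0)
            else:
                mu, var = bn.run_mean[i], bn.run_var[i]
            zh = (z - mu) / np.sqrt(var + _BN_EPS)
            zo = bn.gamma[i] * zh + bn.beta[i]
        else:
            mu = var = zh = None
            zo = z
        a = np.maximum(zo, 0.0)
        if dropout_masks is not None and dropout_masks[i + 1] is not None:
            a = a * dropout_masks[i + 1]
        activations.append(a)
        caches.append((z, mu, var, zh, zo))
    z_out = a @ weights[-1] + biases[-1]
    return activations, caches, _sigmoid(z_out)


def loss_and_grads(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    X: np.ndarray,
    Y: np.ndarray,
    l1_lambda: float,
    dropout_masks: list[np.ndarray | None] | None = None,
    bn: BatchNormState | None = None,
):
    """Penalized loss and its analytic gradients.

    The RMSE term uses d RMSE / d yhat = (yhat - y) / (N * RMSE); the L1
    term contributes lambda * sign(W) (subgradient 0 at exact zeros).
    With ``bn`` given, batch statistics are used (training mode) and
    gradients w.r.t. the scale/shift parameters are returned as well;
    batch means/variances are returned so the caller can maintain running
    statistics.  Returns (loss, grads) with grads a dict holding keys
    "w", "b", and, when bn is given, "gamma", "beta", "batch_stats".
    """
    N = X.shape[0]
    activations, caches, y_hat = _forward(
        weights, biases, X, dropout_masks, bn=bn, bn_batch_stats=True
    )
    r = rmse(Y, y_hat)
    loss = r + l1_lambda * l1_penalty(weights)
    grads: dict = {
        "w": [np.zeros_like(w) for w in weights],
        "b": [np.zeros_like(b) for b in biases],
    }
    if bn is not None:
        grads["gamma"] = [np.zeros_like(g) for g in bn.gamma]
        grads["beta"] = [np.zeros_like(b) for b in bn.beta]
        grads["batch_stats"] = [(c[1], c[2]) for c in caches]
    # residual gradient; at a perfect fit the RMSE term is at its minimum
    # and only the (sub)gradient of the L1 penalty remains
    if r > 0:
        delta = (y_hat - Y) / (N * r) * (y_hat * (1.0 - y_hat))
        grads["w"][-1] = activations[-1].T @ delta
        grads["b"][-1] = delta.sum(axis=0)
        da = delta @ weights[-1].T
        for i in range(len(caches) - 1, -1, -1):
            z, mu, var, zh, zo = caches[i]
            if dropout_masks is not None and dropout_masks[i + 1] is not None:
                da = da * dropout_masks[i + 1]
            dzo = da * (zo > 0)
            if bn is not None:
                m = z.shape[0]
                std = np.sqrt(var + _BN_EPS)
                grads["gamma"][i] = (dzo * zh).sum(axis=0)
                grads["beta"][i] = dzo.sum(axis=0)
                dzh = dzo * bn.gamma[i]
                dvar = (dzh * (z - mu)).sum(axis=0) * (-0.5) * std**-3
                dmu = (-dzh / std).sum(axis=0) + dvar * (-2.0) * (z - mu).mean(axis=0)
                dz = dzh / std + dvar * 2.0 * (z - mu) / m + dmu / m
            else:
                dz = dzo
            grads["w"][i] = activations[i].T @ dz
            grads["b"][i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ weights[i].T
    for i, w in enumerate(weights):
        grads["w"][i] = grads["w"][i] + l1_lambda * np.sign(w)
    return loss, grads


def _draw_dropout_masks(
    spec: ModelSpec, n_rows: int, rng: np.random.Generator
) -> list[np.ndarray | None]:
    """Inverted-dropout masks for the input and first hidden activations."""
    rate = spec.dropout_rate
    n_hidden = len(spec.hidden_widths)
    masks: list[np.ndarray | None] = [None] * (n_hidden + 1)
    if rate == 0.0:
        return masks
    keep = 1.0 - rate
    sizes = spec.layer_sizes
    for layer in range(min(_N_DROPOUT_HIDDEN, n_hidden) + 1):  # input + hidden[:5]
        masks[layer] = (
            rng.random((n_rows, sizes[layer])) < keep
        ).astype(np.float64) / keep
    return masks


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    """Adam state over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], beta1: float, beta2: float, eps: float):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    model: TrainedModel,
    reference: SpatialDataset,
    normalizer: CoordNormalizer,
    config: TrainConfig,
) -> TrainedModel:
    """Fit the model to a spatial reference dataset.

    ``reference.expr`` must already be depth-normalized and restricted to
    the selected gene set; coordinates are mapped to unit targets with
    ``normalizer``.  Returns a new TrainedModel carrying the optimized
    parameters, per-epoch history and the validation-split mean prediction
    correlation r-bar.
    """
    if reference.coords is None:
        raise ValidationError("reference dataset has no coordinates")
    if reference.n_genes != model.spec.n_genes:
        raise ValidationError(
            f"dataset has {reference.n_genes} genes, model expects {model.spec.n_genes}"
        )
    X = reference.dense_expr()
    Y = normalize_coords(reference.coords, normalizer)
    if Y.shape[1] != model.spec.out_dim:
        raise ValidationError("coordinate dimensionality does not match model out_dim")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_val = max(1, int(round(n * config.validation_fraction)))
    if n - n_val < 1:
        raise ValidationError("not enough observations for a validation split")
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    batch_size = config.batch_size
    if batch_size > len(tr_idx):
        warnings.warn(
            f"batch_size {batch_size} exceeds training-set size {len(tr_idx)}; clamped",
            stacklevel=2,
        )
        batch_size = len(tr_idx)

    spec = model.spec
    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    bn = model.bn.copy() if model.bn is not None else None
    flat_params = weights + biases + (bn.gamma + bn.beta if bn is not None else [])
    adam = _Adam(flat_params, config.beta1, config.beta2, config.eps)
    lr = config.learning_rate

    history: dict = {"loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = None
    epochs_no_improve = 0
    lr_no_improve = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            masks = _draw_dropout_masks(spec, len(batch), rng)
            loss, grads = loss_and_grads(
                weights, biases, X_tr[batch], Y_tr[batch], spec.l1_lambda, masks, bn=bn
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, lr {lr:.3g}; aborting"
                )
            flat_grads = grads["w"] + grads["b"] + (
                grads["gamma"] + grads["beta"] if bn is not None else []
            )
            adam.step(flat_grads, lr)
            if bn is not None:
                for i, (mu, var) in enumerate(grads["batch_stats"]):
                    bn.run_mean[i] = _BN_MOMENTUM * bn.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                    bn.run_var[i] = _BN_MOMENTUM * bn.run_var[i] + (1 - _BN_MOMENTUM) * var

        # epoch-level penalized losses, inference mode (no dropout,
        # running batch-norm statistics)
        _, _, yhat_tr = _forward(weights, biases, X_tr, bn=bn)
        _, _, yhat_val = _forward(weights, biases, X_val, bn=bn)
        tr_loss = total_loss(Y_tr, yhat_tr, weights, spec.l1_lambda)
        val_loss = total_loss(Y_val, yhat_val, weights, spec.l1_lambda)
        history["loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = (
                [w.copy() for w in weights],
                [b.copy() for b in biases],
                bn.copy() if bn is not None else None,
            )
            epochs_no_improve = 0
            lr_no_improve = 0
        else:
            epochs_no_improve += 1
            lr_no_improve += 1
        if lr_no_improve >= config.lr_patience and lr > config.min_lr:
            lr = max(lr * config.lr_factor, config.min_lr)
            lr_no_improve = 0
            logger.info("epoch %d: reducing learning rate to %.3g", epoch, lr)
        if epochs_no_improve >= config.early_stopping_patience:
            logger.info("early stopping at epoch %d (best val loss %.5g)", epoch, best_val)
            break

    if config.restore_best and best_state is not None:
        weights, biases, bn = best_state

    trained = TrainedModel(
        spec=replace(spec),
        weights=weights,
        biases=biases,
        bn=bn,
        gene_ids=list(reference.gene_ids),
        history=history,
    )
    _, _, yhat_val = _forward(weights, biases, X_val, bn=bn)
    trained.mean_pred_corr = _mean_axis_pearson(Y_val, yhat_val)
    return trained


def _mean_axis_pearson(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean over coordinate axes of Pearson r(truth, prediction)."""
    rs = []
    for axis in range(y.shape[1]):
        a, b = y[:, axis], y_hat[:, axis]
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(rs)) if rs else 0.0


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(
    model: TrainedModel,
    expr: SpatialDataset | np.ndarray,
    mc_dropout: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Predict unit-interval coordinates for each observation.

    Dropout is off by default, giving a deterministic point prediction.
    ``mc_dropout=S`` instead averages S stochastic forward passes with
    dropout active (Monte-Carlo dropout), seeded for reproducibility.
    When ``expr`` is a SpatialDataset its gene ids must equal the model's
    training gene list, order included — there is no silent reindexing.
    """
    if isinstance(expr, SpatialDataset):
        if model.gene_ids is not None and expr.gene_ids != model.gene_ids:
            raise ValidationError(
                "query gene ids do not match the model's training gene list "
                "(order matters); subset/reorder explicitly before predicting"
            )
        X = expr.dense_expr()
    else:
        X = np.asarray(expr, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != model.spec.n_genes:
        raise ValidationError(
            f"expression has {X.shape[1]} genes, model expects {model.spec.n_genes}"
        )
    if mc_dropout <= 0:
        _, _, y_hat = _forward(model.weights, model.biases, X, bn=model.bn)
        return y_hat
    rng = np.random.default_rng(seed)
    acc = np.zeros((X.shape[0], model.spec.out_dim))
    for _ in range(mc_dropout):
        masks = _draw_dropout_masks(model.spec, X.shape[0], rng)
        _, _, y_hat = _forward(model.weights, model.biases, X, masks, bn=model.bn)
        acc += y_hat
    return acc / mc_dropout


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(
    model: TrainedModel,
    path,
    normalizer: CoordNormalizer | None = None,
) -> None:
    """Persist weights, spec, gene list and (optionally) the coordinate
    normalizer in a single HDF5 container."""
    with h5py.File(path, "w") as f:
        spec_grp = f.create_group("spec")
        spec_grp.attrs["n_genes"] = model.spec.n_genes
        spec_grp.attrs["out_dim"] = model.spec.out_dim
        spec_grp.attrs["hidden_widths"] = list(model.spec.hidden_widths)
        spec_grp.attrs["dropout_rate"] = model.spec.dropout_rate
        spec_grp.attrs["l1_lambda"] = model.spec.l1_lambda
        spec_grp.attrs["batch_norm"] = model.spec.batch_norm
        for i, (w, b) in enumerate(zip(model.weights, model.biases)):
            f.create_dataset(f"weights/{i}", data=w)
            f.create_dataset(f"biases/{i}", data=b)
        if model.bn is not None:
            for i in range(len(model.bn.gamma)):
                f.create_dataset(f"bn/gamma/{i}", data=model.bn.gamma[i])
                f.create_dataset(f"bn/beta/{i}", data=model.bn.beta[i])
                f.create_dataset(f"bn/run_mean/{i}", data=model.bn.run_mean[i])
                f.create_dataset(f"bn/run_var/{i}", data=model.bn.run_var[i])
        if model.gene_ids is not None:
            f.create_dataset(
                "gene_ids", data=np.array(model.gene_ids, dtype=h5py.string_dtype())
            )
        if model.mean_pred_corr is not None:
            f.attrs["mean_pred_corr"] = model.mean_pred_corr
        for key in ("loss", "val_loss", "lr"):
            if model.history.get(key):
                f.create_dataset(f"history/{key}", data=np.asarray(model.history[key]))
        if normalizer is not None:
            ng = f.create_group("normalizer")
            ng.attrs["system"] = normalizer.system
            ng.create_dataset("mins", data=normalizer.mins)
            ng.create_dataset("maxs", data=normalizer.maxs)
            if normalizer.polar_center is not None:
                ng.create_dataset("polar_center", data=normalizer.polar_center)


def load_model(path) -> tuple[TrainedModel, CoordNormalizer | None]:
    """Inverse of :func:`save_model`."""
    with h5py.File(path, "r") as f:
        spec = ModelSpec(
            n_genes=int(f["spec"].attrs["n_genes"]),
            out_dim=int(f["spec"].attrs["out_dim"]),
            hidden_widths=tuple(int(w) for w in f["spec"].attrs["hidden_widths"]),
            dropout_rate=float(f["spec"].attrs["dropout_rate"]),
            l1_lambda=float(f["spec"].attrs["l1_lambda"]),
            batch_norm=bool(f["spec"].attrs["batch_norm"]),
        )
        n_mats = len(spec.hidden_widths) + 1
        weights = [np.asarray(f[f"weights/{i}"]) for i in range(n_mats)]
        biases = [np.asarray(f[f"biases/{i}"]) for i in range(n_mats)]
        bn = None
        if "bn" in f:
            n_h = len(spec.hidden_widths)
            bn = BatchNormState(
                gamma=[np.asarray(f[f"bn/gamma/{i}"]) for i in range(n_h)],
                beta=[np.asarray(f[f"bn/beta/{i}"]) for i in range(n_h)],
                run_mean=[np.asarray(f[f"bn/run_mean/{i}"]) for i in range(n_h)],
                run_var=[np.asarray(f[f"bn/run_var/{i}"]) for i in range(n_h)],
            )
        gene_ids = None
        if "gene_ids" in f:
            gene_ids = [
                g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][:]
            ]
        history = {}
        if "history" in f:
            history = {k: list(np.asarray(f[f"history/{k}"])) for k in f["history"]}
        model = TrainedModel(
            spec=spec,
            weights=weights,
            biases=biases,
            bn=bn,
            gene_ids=gene_ids,
            history=history,
            mean_pred_corr=float(f.attrs["mean_pred_corr"])
            if "mean_pred_corr" in f.attrs
            else None,
        )
        normalizer = None
        if "normalizer" in f:
            ng = f["normalizer"]
            normalizer = CoordNormalizer(
                system=str(ng.attrs["system"]),
                mins=np.asarray(ng["mins"]),
                maxs=np.asarray(ng["maxs"]),
                polar_center=np.asarray(ng["polar_center"]) if "polar_center" in ng else None,
            )
    return model, normalizer
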