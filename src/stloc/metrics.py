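"""Evaluation statistics and the cross-validation driver.

Mapping accuracy is scored with rotation/translation-invariant pairwise
metrics: the vector of all n(n-1)/2 Euclidean distances among the true
positions is compared with the same vector for the predicted positions
(canonical i < j, row-major pair ordering), by Pearson correlation
(pairwise r) and root-mean-square difference (pairwise RMSE).  Both
coordinate sets are expected on the min-max-normalized scale, so RMSE is
unit-free; rigid motions of either set leave both metrics unchanged
because they only move through the distance vectors.

Spatial structure of expression is scored with Moran's I

    I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

and consistency between reference and reconstructed expression with the
bivariate Moran's I (BVI), which replaces the second factor by a second
variable and standardizes by both standard deviations.  Spatial weights
are either inverse-distance (w_ij = 100 / d_ij for pairs closer than a
threshold, 0 otherwise — the scheme used for BVI) or binary symmetric
k-nearest-neighbor graphs (the convention for per-gene Moran's I,
default k = 6).  Constant inputs make these statistics undefined and
raise, never silently return 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

from .core_data import SpatialDataset, fit_coord_normalizer, normalize_coords
from .errors import UndefinedStatisticError, ValidationError
from .model import ModelSpec, TrainConfig, build_model, predict, train

__all__ = [
    "SpatialWeights",
    "build_spatial_weights",
    "default_bvi_threshold",
    "morans_i",
    "bivariate_morans_i",
    "pairwise_distances",
    "pairwise_pearson_r",
    "pairwise_rmse",
    "CVResult",
    "crossvalidate",
]

logger = logging.getLogger(__name__)

# inverse-distance weights use this numerator as a scale factor
_INV_DIST_SCALE = 100.0


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Sparse symmetric non-negative spatial weight matrix, zero diagonal."""

    mode: str
    pairs: sp.csr_matrix
    threshold: float | None = None
    k: int | None = None

    @property
    def total(self) -> float:
        return float(self.pairs.sum())


def build_spatial_weights(
    coords: np.ndarray,
    mode: str = "knn",
    threshold: float | None = None,
    k: int | None = None,
) -> SpatialWeights:
    """Build a spatial weight matrix over observation coordinates.

    mode="inverse-distance": w_ij = 100 / d_ij for d_ij < threshold, else 0
    (duplicate coordinates are an error — the weight would be infinite).
    mode="knn": binary symmetric union of k-nearest-neighbor relations
    (default k = 6).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need at least 2 observations")
    n = coords.shape[0]
    if mode == "inverse-distance":
        if threshold is None or threshold <= 0:
            raise ValidationError("inverse-distance mode requires a positive threshold")
        d = pdist(coords)
        rows, cols = np.triu_indices(n, k=1)
        hit = d < threshold
        dup = hit & (d == 0)
        if dup.any():
            i, j = rows[dup][0], cols[dup][0]
            raise ValidationError(
                f"duplicate coordinates for observations {i} and {j}: "
                "inverse-distance weight undefined"
            )
        w = np.zeros_like(d)
        w[hit] = _INV_DIST_SCALE / d[hit]
        mat = sp.coo_matrix((w[hit], (rows[hit], cols[hit])), shape=(n, n))
        mat = (mat + mat.T).tocsr()
        return SpatialWeights(mode=mode, pairs=mat, threshold=float(threshold))
    if mode == "knn":
        if k is None:
            k = 6
        if not 1 <= k < n:
            raise ValidationError(f"k must be in [1, {n - 1}]")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        graph = nn.kneighbors_graph(coords, mode="connectivity")
        graph.setdiag(0)
        graph.eliminate_zeros()
        sym = graph.maximum(graph.T)  # union of neighbor relations, binary
        return SpatialWeights(mode=mode, pairs=sp.csr_matrix(sym), k=int(k))
    raise ValidationError(f"unknown spatial weights mode: {mode!r}")


def default_bvi_threshold(coords: np.ndarray) -> float:
    """Default inverse-distance threshold: 2x the 95th percentile of
    nearest-neighbor distances, so nearly every observation keeps a few
    neighbors.  The choice is logged prominently since it shapes the BVI."""
    coords = np.asarray(coords, dtype=np.float64)
    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    d, _ = nn.kneighbors(coords)
    thr = 2.0 * float(np.percentile(d[:, 1], 95))
    logger.warning("using default BVI distance threshold %.4g (2 x p95 NN distance)", thr)
    return thr


# ---------------------------------------------------------------------------
# Autocorrelation statistics
# ---------------------------------------------------------------------------

def _check_weights(w: SpatialWeights, n: int) -> None:
    if w.pairs.shape != (n, n):
        raise ValidationError(f"weights are {w.pairs.shape}, data has {n} observations")
    if w.total <= 0:
        raise UndefinedStatisticError("spatial weights sum to zero; statistic undefined")


def morans_i(x: np.ndarray, w: SpatialWeights) -> float:
    """Global spatial autocorrelation of one variable."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    _check_weights(w, n)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise UndefinedStatisticError("constant input: Moran's I undefined")
    num = float(xc @ (w.pairs @ xc))
    return n / w.total * num / denom


def bivariate_morans_i(x: np.ndarray, y: np.ndarray, w: SpatialWeights) -> float:
    """Cross-variable spatial autocorrelation on a shared spatial support.

    Reduces exactly to :func:`morans_i` when y == x, and is invariant to
    positive affine rescaling of either variable.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    n = x.size
    _check_weights(w, n)
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(float(xc @ xc)), np.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("constant input: bivariate Moran's I undefined")
    num = float(xc @ (w.pairs @ yc))
    return n / w.total * num / (sx * sy)


# ---------------------------------------------------------------------------
# Pairwise mapping-accuracy metrics
# ---------------------------------------------------------------------------

def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """All n(n-1)/2 Euclidean distances, canonical (i < j) ordering."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    return pdist(coords)


def pairwise_pearson_r(true_coords: np.ndarray, pred_coords: np.ndarray) -> float:
    """Pearson r between true and predicted pairwise-distance vectors.

    Invariant to rigid motions of either coordinate set.  Coordinates are
    expected min-max normalized (the convention for reporting).
    """
    dt, dp = _paired_distance_vectors(true_coords, pred_coords, min_points=3)
    if dt.std() == 0 or dp.std() == 0:
        raise UndefinedStatisticError(
            "a pairwise-distance vector has zero variance; Pearson r undefined"
        )
    return float(np.corrcoef(dt, dp)[0, 1])


def pairwise_rmse(true_coords: np.ndarray, pred_coords: np.ndarray) -> float:
    """Root-mean-square difference between the pairwise-distance vectors."""
    dt, dp = _paired_distance_vectors(true_coords, pred_coords, min_points=2)
    return float(np.sqrt(np.mean((dt - dp) ** 2)))


def _paired_distance_vectors(true_coords, pred_coords, min_points: int):
    true_coords = np.asarray(true_coords, dtype=np.float64)
    pred_coords = np.asarray(pred_coords, dtype=np.float64)
    if true_coords.shape[0] != pred_coords.shape[0]:
        raise ValidationError("true and predicted coordinate counts differ")
    if true_coords.shape[0] < min_points:
        raise ValidationError(f"need at least {min_points} points")
    return pdist(true_coords), pdist(pred_coords)


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold and pooled leave-out mapping metrics.

    ``pooled_pred`` holds unit-scale predictions in original observation
    order; ``pooled_true`` the matching normalized true coordinates.
    Optional bootstrap summaries resample the pooled leave-out
    observations with replacement and recompute both metrics.
    """

    fold_r: list[float]
    fold_rmse: list[float]
    pooled_r: float
    pooled_rmse: float
    pooled_pred: np.ndarray
    pooled_true: np.ndarray
    fold_assignment: np.ndarray
    bootstrap: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.fold_r))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))


def crossvalidate(
    dataset: SpatialDataset,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    bootstrap_reps: int = 0,
) -> CVResult:
    """K-fold cross-validated location prediction.

    The coordinate normalizer is fitted once on the full dataset (the
    coordinate frame, not the labels of individual folds), folds are a
    seeded disjoint partition, and for each fold a fresh model is trained
    on the remainder and evaluated on the leave-out set with pairwise
    Pearson r and pairwise RMSE on normalized coordinates.  Pooled metrics
    use the concatenated leave-out predictions of all folds.
    """
    if dataset.coords is None:
        raise ValidationError("dataset has no coordinates")
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    n = dataset.n_obs
    if n // n_folds < 3:
        raise ValidationError("folds must contain at least 3 observations")

    normalizer = fit_coord_normalizer(dataset.coords, system="cartesian")
    true_unit = normalize_coords(dataset.coords, normalizer)
    pooled_pred = np.zeros_like(true_unit)
    fold_assignment = np.zeros(n, dtype=int)

    fold_r: list[float] = []
    fold_rmse: list[float] = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (tr_idx, te_idx) in enumerate(kf.split(np.arange(n))):
        train_set = dataset.subset_obs(tr_idx)
        cfg = replace(train_config, seed=int(train_config.seed + 1000 * fold + 1))
        model = build_model(model_spec, seed=cfg.seed)
        model = train(model, train_set, normalizer, cfg)
        pred = predict(model, dataset.dense_expr()[te_idx])
        pooled_pred[te_idx] = pred
        fold_assignment[te_idx] = fold
        fold_r.append(pairwise_pearson_r(true_unit[te_idx], pred))
        fold_rmse.append(pairwise_rmse(true_unit[te_idx], pred))
        logger.info(
            "fold %d: pairwise r %.4f, pairwise RMSE %.4f", fold, fold_r[-1], fold_rmse[-1]
        )

    result = CVResult(
        fold_r=fold_r,
        fold_rmse=fold_rmse,
        pooled_r=pairwise_pearson_r(true_unit, pooled_pred),
        pooled_rmse=pairwise_rmse(true_unit, pooled_pred),
        pooled_pred=pooled_pred,
        pooled_true=true_unit,
        fold_assignment=fold_assignment,
    )
    if bootstrap_reps > 0:
        result.bootstrap = _bootstrap_metrics(true_unit, pooled_pred, bootstrap_reps, seed)
    return result


def _bootstrap_metrics(
    true_unit: np.ndarray, pred: np.ndarray, reps: int, seed: int
) -> dict:
    """Resample observations (spatial voxels) with replacement, same size."""
    rng = np.random.default_rng(seed)
    n = true_unit.shape[0]
    rs, rmses = [], []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        # duplicated voxels give zero-distance pairs in both vectors; fine
        try:
            rs.append(pairwise_pearson_r(true_unit[idx], pred[idx]))
        except UndefinedStatisticError:  # pragma: no cover - pathological resample
            continue
        rmses.append(pairwise_rmse(true_unit[idx], pred[idx]))
    return {
        "reps": reps,
        "r_mean": float(np.mean(rs)),
        "r_sd": float(np.std(rs, ddof=1)),
        "rmse_mean": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses, ddof=1)),
    }
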