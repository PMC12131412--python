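"""Gene-importance scoring by backward aggregation of trained weights.

Training with an L1 penalty shrinks weights that do not contribute to
location prediction toward zero, so the surviving large weights carry the
spatial signal.  Gene importance is read off the trained network by
walking the weight matrices backward from the output:

* for the last weight matrix (index I), each row's score is the plain sum
  of absolute weights, S_{I,j} = sum_k |W_{I,j,k}|;
* for every earlier matrix i, only columns k whose downstream node score
  exceeds the r-th percentile of S_{i+1} (default r = 50) are kept:
  S_{i,j} = sum_k 1[S_{i+1,k} > Percentile(S_{i+1}, r)] * |W_{i,j,k}|.

Columns of W_i and rows of W_{i+1} index the same hidden nodes, so the
mask gates matrix i's columns by the scores of matrix i+1's rows.  The
result S_1 has one non-negative score per input gene.  Scores are then
normalized to sum to r-bar * Scaler (Scaler default 1000), where r-bar is
the model's mean prediction-truth Pearson correlation, so rankings from
better-fitting models carry proportionally larger scores.  Genes ranked
highly this way vary spatially — the scores double as a spatially
variable gene (SVG) ranking.  Biases play no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "ImportanceScores",
    "backtrack_importance",
    "normalize_importance",
    "rank_svgs",
    "score_genes",
]


@dataclass
class ImportanceScores:
    """Raw and normalized per-gene importance scores."""

    gene_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    percentile_r: float = 50.0
    scaler: float = 1000.0
    mean_corr: float = 0.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.normalized = np.asarray(self.normalized, dtype=np.float64)
        if not (len(self.gene_ids) == self.raw.size == self.normalized.size):
            raise ValidationError("gene_ids, raw and normalized must align")
        if (self.raw < 0).any():
            raise ValidationError("raw scores must be non-negative")


def _check_chain(weights: list[np.ndarray]) -> None:
    if not weights:
        raise ValidationError("at least one weight matrix is required")
    for i in range(len(weights) - 1):
        if weights[i].shape[1] != weights[i + 1].shape[0]:
            raise ValidationError(
                f"weight shape chain broken between matrices {i} and {i + 1}: "
                f"{weights[i].shape} -> {weights[i + 1].shape}"
            )


def backtrack_importance(
    weights: list[np.ndarray], percentile_r: float = 50.0
) -> np.ndarray:
    """Raw gene scores S_1 by masked backward weight aggregation.

    Percentiles use linear interpolation between order statistics (the
    common median convention at r = 50); the mask keeps scores strictly
    above the threshold.  All node scores, including exact zeros, enter
    the percentile.
    """
    weights = [np.asarray(w, dtype=np.float64) for w in weights]
    _check_chain(weights)
    if not 0 < percentile_r < 100:
        raise ValidationError("percentile_r must be in (0, 100)")
    s = np.abs(weights[-1]).sum(axis=1)  # unmasked base case, last matrix
    for w in weights[-2::-1]:
        thresh = np.percentile(s, percentile_r)
        mask = (s > thresh).astype(np.float64)
        s = np.abs(w) @ mask
    return s


def normalize_importance(
    raw: np.ndarray, mean_corr: float, scaler: float = 1000.0
) -> np.ndarray:
    """Rescale raw scores so they sum to mean_corr * scaler."""
    raw = np.asarray(raw, dtype=np.float64)
    if scaler <= 0:
        raise ValidationError("scaler must be positive")
    total = raw.sum()
    if total <= 0:
        raise ValidationError(
            "all raw importance scores are zero (degenerate model); "
            "nothing to normalize"
        )
    return raw / total * mean_corr * scaler


def rank_svgs(scores: ImportanceScores, top_n: int | None = None) -> list[str]:
    """Gene ids sorted by normalized score descending; ties broken by id."""
    if top_n is None:
        top_n = len(scores.gene_ids)
    if top_n > len(scores.gene_ids):
        raise ValidationError("top_n exceeds the number of genes")
    order = sorted(
        range(len(scores.gene_ids)),
        key=lambda i: (-scores.normalized[i], scores.gene_ids[i]),
    )
    return [scores.gene_ids[i] for i in order[:top_n]]


def score_genes(
    model,
    percentile_r: float = 50.0,
    scaler: float = 1000.0,
) -> ImportanceScores:
    """Backtrack a trained model's weights into an ImportanceScores table.

    ``model`` is a :class:`~stloc.model.TrainedModel` with gene_ids and a
    validation mean prediction correlation r-bar set by training.
    """
    raw = backtrack_importance(model.weights, percentile_r)
    r_bar = model.mean_pred_corr if model.mean_pred_corr is not None else 0.0
    normalized = normalize_importance(raw, r_bar, scaler)
    gene_ids = model.gene_ids or [f"g{i}" for i in range(raw.size)]
    return ImportanceScores(
        gene_ids=list(gene_ids),
        raw=raw,
        normalized=normalized,
        percentile_r=percentile_r,
        scaler=scaler,
        mean_corr=r_bar,
    )
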