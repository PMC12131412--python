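"""Expression normalization and Wasserstein-distance gene selection.

Counts are depth-normalized to a fixed total per observation (default
10,000) and log-transformed with ln(1 + x).  When a query dataset from a
different batch (e.g. scRNA-seq) is to be mapped onto a spatial reference,
genes whose expression distributions differ strongly between the two
batches are removed: for each shared gene the 1D Wasserstein distance
W1(u, v) = integral |U - V| between the empirical CDFs of its normalized
expression in reference (u) and query (v) is computed, and only genes with
W1 below a threshold (default 0.1) are kept for training.  A constant
shift of c in the normalized values moves W1 by exactly |c|, so the filter
removes additively batch-shifted genes while keeping genes whose
distributions merely fluctuate by sampling.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.stats import wasserstein_distance

from .core_data import SpatialDataset
from .errors import ValidationError

__all__ = [
    "normalize_counts",
    "wasserstein_1d",
    "intersect_genes",
    "select_genes",
]

logger = logging.getLogger(__name__)


def normalize_counts(dataset: SpatialDataset, target_sum: float = 10_000.0) -> SpatialDataset:
    """Depth-normalize each observation to ``target_sum`` and apply ln(1+x).

    Returns a new dataset; the input is unmodified.  Observations with an
    all-zero expression row cannot be depth-normalized and raise
    :class:`ValidationError` naming the offending observation ids.
    """
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    expr = dataset.dense_expr()
    if expr.size and expr.min() < 0:
        raise ValidationError("expression contains negative entries; expected raw counts")
    row_sums = expr.sum(axis=1)
    zero_rows = np.nonzero(row_sums == 0)[0]
    if zero_rows.size:
        bad = [dataset.obs_ids[i] for i in zero_rows[:10]]
        raise ValidationError(
            f"{zero_rows.size} observation(s) with zero total counts: {bad}"
        )
    scaled = expr * (target_sum / row_sums)[:, None]
    out = dataset.copy()
    out.expr = np.log1p(scaled)
    return out


def wasserstein_1d(u: np.ndarray, v: np.ndarray) -> float:
    """1D Wasserstein (earth-mover's) distance between empirical samples.

    Equal-weight empirical CDFs (mass 1/n per observation); unequal sample
    sizes are handled by exact step-function integration.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size == 0 or v.size == 0:
        raise ValidationError("wasserstein_1d requires non-empty samples")
    return float(wasserstein_distance(u, v))


def intersect_genes(a: SpatialDataset, b: SpatialDataset) -> list[str]:
    """Gene ids present in both datasets, in ``a``'s gene order."""
    b_set = set(b.gene_ids)
    return [g for g in a.gene_ids if g in b_set]


def select_genes(
    reference: SpatialDataset,
    query: SpatialDataset,
    threshold: float = 0.1,
) -> list[str]:
    """Shared genes with batch-comparable expression distributions.

    Both datasets must already be normalized (see :func:`normalize_counts`).
    Returns the genes in the reference-query intersection whose Wasserstein
    distance between reference and query expression is strictly below
    ``threshold``, preserving reference gene order.
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    shared = intersect_genes(reference, query)
    if not shared:
        raise ValidationError("reference and query share no genes")
    ref_expr = reference.dense_expr()
    qry_expr = query.dense_expr()
    ref_idx = {g: i for i, g in enumerate(reference.gene_ids)}
    qry_idx = {g: i for i, g in enumerate(query.gene_ids)}
    selected = [
        g
        for g in shared
        if wasserstein_1d(ref_expr[:, ref_idx[g]], qry_expr[:, qry_idx[g]]) < threshold
    ]
    logger.info(
        "select_genes: %d reference genes, %d shared, %d selected (threshold %.3g)",
        reference.n_genes,
        len(shared),
        len(selected),
        threshold,
    )
    return selected
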