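"""Fine mapping: bead assignment and inverse-distance expression reconstruction.

A predicted cell position rarely falls exactly on a reference bead center,
and several cells may land near the same bead.  For visualization and for
consistency scoring against the reference, each bead is reconstructed as
the inverse-distance weighted average of the query cells predicted within
a cutoff radius of its center (15 µm for Slide-seqV2-like, 110 µm for
Visium-like assays):

    w_j = (1 / d_j) / sum_{i=1..k} (1 / d_i)

Cells may contribute to multiple beads; membership is restricted per bead,
not per cell.  A cell predicted exactly at a bead center (d = 0) takes the
limit of the weights: weight 1 for the zero-distance cell(s), 0 elsewhere.
Beads with no cell within the cutoff are marked missing (NaN), never
silently zero, and are excluded from downstream consistency statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_data import SpatialDataset
from .errors import ValidationError

__all__ = [
    "BeadAssignment",
    "assign_to_beads",
    "reconstruction_weights",
    "reconstruct_bead_expression",
]

logger = logging.getLogger(__name__)


@dataclass
class BeadAssignment:
    """Per-bead membership of predicted cells within a distance cutoff.

    ``members[b]`` is a list of (cell index, distance) pairs for bead b;
    distances are in the original (denormalized) coordinate units and
    never exceed ``cutoff``.
    """

    bead_ids: list[str]
    bead_coords: np.ndarray
    members: list[list[tuple[int, float]]]
    cutoff: float

    @property
    def n_beads(self) -> int:
        return len(self.bead_ids)

    def n_unassigned_cells(self, n_cells: int) -> int:
        assigned = {i for mem in self.members for i, _ in mem}
        return n_cells - len(assigned)


def assign_to_beads(
    pred_coords: np.ndarray,
    bead_coords: np.ndarray,
    cutoff: float,
    bead_ids: list[str] | None = None,
) -> BeadAssignment:
    """Attach each predicted cell to every bead within ``cutoff`` (Euclidean).

    Both coordinate sets must be in the same physical units (the cutoff is
    meaningful in µm only after predictions are denormalized with the
    reference coordinate normalizer).
    """
    pred_coords = np.asarray(pred_coords, dtype=np.float64)
    bead_coords = np.asarray(bead_coords, dtype=np.float64)
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if pred_coords.ndim != 2 or bead_coords.ndim != 2:
        raise ValidationError("coordinate matrices must be 2-dimensional")
    if pred_coords.shape[1] != bead_coords.shape[1]:
        raise ValidationError(
            f"dimension mismatch: cells {pred_coords.shape[1]}D vs beads {bead_coords.shape[1]}D"
        )
    if bead_ids is None:
        bead_ids = [f"bead{i}" for i in range(bead_coords.shape[0])]
    if len(bead_ids) != bead_coords.shape[0]:
        raise ValidationError("bead_ids length != number of bead coordinates")

    tree = cKDTree(pred_coords)
    members: list[list[tuple[int, float]]] = []
    for b in range(bead_coords.shape[0]):
        idx = tree.query_ball_point(bead_coords[b], r=cutoff)
        dists = np.linalg.norm(pred_coords[idx] - bead_coords[b], axis=1) if idx else np.empty(0)
        members.append(sorted(zip(idx, dists.tolist())))
    n_unassigned = BeadAssignment(bead_ids, bead_coords, members, cutoff).n_unassigned_cells(
        pred_coords.shape[0]
    )
    if n_unassigned:
        logger.info(
            "assign_to_beads: %d/%d cells fall outside the cutoff of every bead",
            n_unassigned,
            pred_coords.shape[0],
        )
    return BeadAssignment(bead_ids, bead_coords, members, cutoff)


def reconstruction_weights(distances: np.ndarray) -> np.ndarray:
    """Inverse-distance weights w_j = (1/d_j) / sum_i (1/d_i), summing to 1.

    Any exact-zero distance takes the limit: zero-distance members share
    weight 1 equally and all others get 0.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValidationError("at least one member distance is required")
    if (d < 0).any():
        raise ValidationError("distances must be non-negative")
    zero = d == 0
    if zero.any():
        w = np.zeros_like(d)
        w[zero] = 1.0 / zero.sum()
        return w
    inv = 1.0 / d
    return inv / inv.sum()


def reconstruct_bead_expression(
    assignment: BeadAssignment,
    query_expr: np.ndarray | SpatialDataset,
    gene_ids: list[str] | None = None,
) -> SpatialDataset:
    """Weighted-average query expression onto bead centers.

    Each non-empty bead's expression is the convex combination
    sum_j w_j * expr_j of its member cells; empty beads carry NaN rows.
    Output coordinates are the bead centers.
    """
    if isinstance(query_expr, SpatialDataset):
        gene_ids = list(query_expr.gene_ids)
        expr = query_expr.dense_expr()
    else:
        expr = np.asarray(query_expr, dtype=np.float64)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(expr.shape[1])]
    n_cells = expr.shape[0]
    out = np.full((assignment.n_beads, expr.shape[1]), np.nan)
    for b, mem in enumerate(assignment.members):
        if not mem:
            continue
        idx = [i for i, _ in mem]
        if max(idx) >= n_cells:
            raise ValidationError(
                f"bead {assignment.bead_ids[b]} references cell {max(idx)} "
                f">= {n_cells} query cells"
            )
        w = reconstruction_weights(np.array([d for _, d in mem]))
        out[b] = w @ expr[idx]
    return SpatialDataset(
        expr=out,  # NaN rows mark empty beads
        gene_ids=gene_ids,
        obs_ids=list(assignment.bead_ids),
        coords=assignment.bead_coords.copy(),
    )
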