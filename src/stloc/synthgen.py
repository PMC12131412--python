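"""Synthetic spatial-transcriptomics data with known ground truth.

Every pipeline stage is testable without downloads: the generator places
spots in a known bounding box (1000 x 1000 µm by default), gives a chosen
minority of genes smooth spatial intensity surfaces (linear gradients,
Gaussian bumps, concentric rings, half-plane steps) and the rest a
spatially constant intensity, and draws counts from a negative binomial
so overdispersion — the realistic single-cell regime — is controllable.
Per-spot sequencing depth varies lognormally around ``mean_depth``.

Pattern surfaces share a common dynamic range (intensities in
[0.25, 1.75] around the constant noise level 1.0) so the difficulty of
recovering a spatially variable gene is set by dispersion and depth, not
by amplitude differences between pattern kinds.

A paired query set emulates scRNA-seq from the same tissue: cells at new
random positions (withheld from the returned dataset, recorded in the
ground truth) with expression from the same surfaces, optionally with an
additive batch shift on chosen genes applied on the post-normalization
(log) scale — the exact translation the Wasserstein gene filter targets.
Ground truth is kept in a sidecar record, never inside the expression
container, so it cannot leak into training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import SpatialDataset
from .errors import ValidationError
from .preprocess import normalize_counts

__all__ = ["SynthConfig", "GroundTruth", "generate_reference", "generate_query"]

_PATTERN_KINDS = ("linear-gradient", "gaussian-bump", "concentric-ring", "half-plane-step")
_BOX = 1000.0  # µm, square bounding box side
# intensity surfaces span [1-_AMPLITUDE, 1+_AMPLITUDE] around the noise level 1.0
_AMPLITUDE = 0.75


@dataclass
class SynthConfig:
    """Study conditions for one synthetic tissue."""

    n_spots: int = 1500
    layout: str = "uniform-random"  # uniform-random | grid | annulus
    n_genes: int = 150
    n_svg: int = 40
    pattern_kinds: tuple[str, ...] = _PATTERN_KINDS
    mean_depth: float = 2000.0
    dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    batch_shift_genes: int = 0
    batch_shift_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_svg > self.n_genes:
            raise ValidationError("n_svg must not exceed n_genes")
        if self.batch_shift_genes > self.n_genes:
            raise ValidationError("batch_shift_genes must not exceed n_genes")
        if self.layout not in ("uniform-random", "grid", "annulus"):
            raise ValidationError(f"unknown layout: {self.layout!r}")
        bad = [k for k in self.pattern_kinds if k not in _PATTERN_KINDS]
        if bad:
            raise ValidationError(f"unknown pattern kinds: {bad}")
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValidationError("mean_depth and dispersion must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    svg_ids: list[str]
    patterns: dict  # gene id -> {"kind": ..., parameters}
    coords: np.ndarray  # reference spot positions
    query_coords: np.ndarray | None = None
    shifted_gene_ids: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        record = {
            "svg_ids": self.svg_ids,
            "patterns": self.patterns,
            "coords": self.coords.tolist(),
            "query_coords": None if self.query_coords is None else self.query_coords.tolist(),
            "shifted_gene_ids": self.shifted_gene_ids,
        }
        Path(path).write_text(json.dumps(record))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        record = json.loads(Path(path).read_text())
        return cls(
            svg_ids=record["svg_ids"],
            patterns=record["patterns"],
            coords=np.asarray(record["coords"], dtype=np.float64),
            query_coords=None
            if record["query_coords"] is None
            else np.asarray(record["query_coords"], dtype=np.float64),
            shifted_gene_ids=record["shifted_gene_ids"],
        )


# ---------------------------------------------------------------------------
# Layouts and intensity surfaces
# ---------------------------------------------------------------------------

def _make_positions(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_spots
    if config.layout == "uniform-random":
        return rng.uniform(0.0, _BOX, size=(n, 2))
    if config.layout == "grid":
        side = int(np.ceil(np.sqrt(n)))
        xs, ys = np.meshgrid(np.linspace(0, _BOX, side), np.linspace(0, _BOX, side))
        pts = np.column_stack([xs.ravel(), ys.ravel()])[:n]
        return pts
    # annulus: radii in [0.25, 0.5] * box, uniform by area
    theta = rng.uniform(-np.pi, np.pi, size=n)
    r = np.sqrt(rng.uniform((0.25 * _BOX) ** 2, (0.5 * _BOX) ** 2, size=n))
    return np.column_stack(
        [_BOX / 2 + r * np.cos(theta), _BOX / 2 + r * np.sin(theta)]
    )


def _sample_pattern(kind: str, rng: np.random.Generator) -> dict:
    if kind == "linear-gradient":
        angle = rng.uniform(-np.pi, np.pi)
        return {"kind": kind, "angle": float(angle)}
    if kind == "gaussian-bump":
        return {
            "kind": kind,
            "cx": float(rng.uniform(0.2 * _BOX, 0.8 * _BOX)),
            "cy": float(rng.uniform(0.2 * _BOX, 0.8 * _BOX)),
            "sigma": float(rng.uniform(0.10 * _BOX, 0.25 * _BOX)),
        }
    if kind == "concentric-ring":
        return {
            "kind": kind,
            "cx": float(rng.uniform(0.3 * _BOX, 0.7 * _BOX)),
            "cy": float(rng.uniform(0.3 * _BOX, 0.7 * _BOX)),
            "radius": float(rng.uniform(0.15 * _BOX, 0.4 * _BOX)),
            "width": float(rng.uniform(0.05 * _BOX, 0.12 * _BOX)),
        }
    if kind == "half-plane-step":
        angle = rng.uniform(-np.pi, np.pi)
        return {"kind": kind, "angle": float(angle), "offset": float(rng.uniform(0.35, 0.65))}
    raise ValidationError(f"unknown pattern kind: {kind!r}")


def _pattern_surface(params: dict, coords: np.ndarray) -> np.ndarray:
    """Relative intensity in [1 - A, 1 + A] at each position."""
    x, y = coords[:, 0] / _BOX, coords[:, 1] / _BOX
    kind = params["kind"]
    if kind == "linear-gradient":
        t = x * np.cos(params["angle"]) + y * np.sin(params["angle"])
        lo, hi = t.min(), t.max()
        unit = (t - lo) / (hi - lo) if hi > lo else np.full_like(t, 0.5)
    elif kind == "gaussian-bump":
        d2 = (coords[:, 0] - params["cx"]) ** 2 + (coords[:, 1] - params["cy"]) ** 2
        unit = np.exp(-d2 / (2 * params["sigma"] ** 2))
    elif kind == "concentric-ring":
        r = np.hypot(coords[:, 0] - params["cx"], coords[:, 1] - params["cy"])
        unit = np.exp(-((r - params["radius"]) ** 2) / (2 * params["width"] ** 2))
    elif kind == "half-plane-step":
        t = x * np.cos(params["angle"]) + y * np.sin(params["angle"])
        lo, hi = t.min(), t.max()
        tt = (t - lo) / (hi - lo) if hi > lo else np.full_like(t, 0.5)
        unit = (tt > params["offset"]).astype(np.float64)
    else:
        raise ValidationError(f"unknown pattern kind: {kind!r}")
    return 1.0 - _AMPLITUDE + 2.0 * _AMPLITUDE * unit


def _intensity_matrix(
    config: SynthConfig, patterns: dict, gene_ids: list[str], coords: np.ndarray
) -> np.ndarray:
    """Spots x genes expected relative intensity; noise genes are flat 1."""
    intensity = np.ones((coords.shape[0], len(gene_ids)))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for gid, params in patterns.items():
        intensity[:, gene_index[gid]] = _pattern_surface(params, coords)
    return intensity


def _draw_counts(
    intensity: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with lognormal per-spot depth factors.

    Mean matrix = depth_s * intensity / row-sum(intensity); NB drawn as a
    gamma-Poisson mixture with size (inverse-dispersion) ``dispersion``:
    var = mu + mu^2 / dispersion.
    """
    depth = config.mean_depth * rng.lognormal(mean=-0.125, sigma=0.5, size=intensity.shape[0])
    proportions = intensity / intensity.sum(axis=1, keepdims=True)
    mu = proportions * depth[:, None]
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    return rng.poisson(lam).astype(np.float64)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_reference(config: SynthConfig) -> tuple[SpatialDataset, GroundTruth]:
    """Generate a spatial reference with known SVGs and positions.

    Returns raw counts; run :func:`~stloc.preprocess.normalize_counts`
    before training, as with real data.
    """
    rng = np.random.default_rng(config.seed)
    coords = _make_positions(config, rng)
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    svg_ids = gene_ids[: config.n_svg]
    patterns = {
        gid: _sample_pattern(config.pattern_kinds[i % len(config.pattern_kinds)], rng)
        for i, gid in enumerate(svg_ids)
    }
    intensity = _intensity_matrix(config, patterns, gene_ids, coords)
    counts = _draw_counts(intensity, config, rng)
    # a spot with zero total counts cannot be depth-normalized; at the
    # default depths this is vanishingly rare, but guard for tiny configs
    zero = counts.sum(axis=1) == 0
    if zero.any():
        counts[zero, 0] = 1.0
    dataset = SpatialDataset(
        expr=counts,
        gene_ids=gene_ids,
        obs_ids=[f"spot{i:05d}" for i in range(config.n_spots)],
        coords=coords,
    )
    truth = GroundTruth(svg_ids=list(svg_ids), patterns=patterns, coords=coords.copy())
    return dataset, truth


def generate_query(
    reference: SpatialDataset,
    truth: GroundTruth,
    config: SynthConfig,
    n_cells: int = 1000,
    seed: int = 1,
) -> tuple[SpatialDataset, GroundTruth]:
    """Emulate a query scRNA-seq set drawn from the same tissue.

    Cells are placed at new random positions in the same bounding box and
    their counts drawn from the same intensity surfaces; the returned
    expression is depth-normalized and log-transformed (the scale on which
    batch shifts act), with ``config.batch_shift_size`` added to the first
    ``config.batch_shift_genes`` genes.  True positions are withheld from
    the dataset and recorded in the returned ground truth, which also
    lists the shifted gene ids.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(n_cells)
    coords = rng.uniform(0.0, _BOX, size=(n_cells, 2))
    intensity = _intensity_matrix(config, truth.patterns, reference.gene_ids, coords)
    counts = _draw_counts(intensity, config, rng)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        counts[zero, 0] = 1.0
    raw = SpatialDataset(
        expr=counts,
        gene_ids=list(reference.gene_ids),
        obs_ids=[f"cell{i:05d}" for i in range(n_cells)],
    )
    query = normalize_counts(raw)
    if config.batch_shift_genes > 0:
        query.expr[:, : config.batch_shift_genes] += config.batch_shift_size
    shifted = list(reference.gene_ids[: config.batch_shift_genes])
    out_truth = GroundTruth(
        svg_ids=list(truth.svg_ids),
        patterns=dict(truth.patterns),
        coords=truth.coords.copy(),
        query_coords=coords,
        shifted_gene_ids=shifted,
    )
    return query, out_truth
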