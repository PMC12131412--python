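"""Data containers, readers/writers, and coordinate normalization.

The central container is :class:`SpatialDataset`: an observations x genes
expression matrix (dense numpy or scipy sparse), gene and observation
identifiers, and optional per-observation spatial coordinates (2D or 3D)
and labels.  Coordinates are continuous real positions (typically µm); no
pixel/array-index convention applies.

Coordinate normalization maps raw positions to the unit interval per axis
(min-max), either directly on Cartesian axes or after conversion to polar
coordinates (radius, angle) about the centroid of the fitted points —
useful for circular tissue sections.  Out-of-range points are mapped
linearly, never clipped; clipping policy belongs to the mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DegenerateGeometryError, ParseError, ValidationError

__all__ = [
    "SpatialDataset",
    "CoordNormalizer",
    "read_dataset",
    "write_dataset",
    "fit_coord_normalizer",
    "normalize_coords",
    "denormalize_coords",
]


# ---------------------------------------------------------------------------
# SpatialDataset
# ---------------------------------------------------------------------------

@dataclass
class SpatialDataset:
    """Expression matrix with identifiers and optional spatial coordinates.

    Parameters
    ----------
    expr
        Observations x genes matrix of non-negative reals (raw counts) or
        reals (after normalization).  Dense ``ndarray`` or scipy sparse.
    gene_ids
        Ordered, unique gene identifiers; one per expression column.
    obs_ids
        Ordered, unique observation (spot/cell) identifiers; one per row.
    coords
        Optional observations x d coordinate matrix, d in {2, 3}.
    labels
        Optional per-observation string labels (e.g. cell types).
    """

    expr: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    obs_ids: list[str]
    coords: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if not sp.issparse(self.expr):
            self.expr = np.asarray(self.expr, dtype=np.float64)
            if self.expr.ndim != 2:
                raise ValidationError("expr must be 2-dimensional")
        n, g = self.expr.shape
        if len(self.obs_ids) != n:
            raise ValidationError(
                f"obs_ids length {len(self.obs_ids)} != {n} expression rows"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != {g} expression columns"
            )
        if len(set(self.gene_ids)) != g:
            dupes = sorted({x for x in self.gene_ids if self.gene_ids.count(x) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:10]}")
        if len(set(self.obs_ids)) != n:
            raise ValidationError("duplicate observation ids")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
                raise ValidationError("coords must be (n_obs, 2) or (n_obs, 3)")
            if self.coords.shape[0] != n:
                raise ValidationError(
                    f"coords rows {self.coords.shape[0]} != {n} observations"
                )
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != n:
                raise ValidationError("labels length != number of observations")

    # -- basic properties ---------------------------------------------------

    @property
    def n_obs(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def dense_expr(self) -> np.ndarray:
        """Expression as a dense float64 array (copy only if sparse)."""
        if sp.issparse(self.expr):
            return np.asarray(self.expr.todense(), dtype=np.float64)
        return self.expr

    # -- subsetting ----------------------------------------------------------

    def subset_genes(self, gene_ids: Sequence[str]) -> "SpatialDataset":
        """Column-subset to ``gene_ids`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"genes not in dataset: {missing[:10]}")
        cols = [index[g] for g in gene_ids]
        expr = self.expr[:, cols] if not sp.issparse(self.expr) else self.expr.tocsc()[:, cols].tocsr()
        return SpatialDataset(
            expr=expr,
            gene_ids=list(gene_ids),
            obs_ids=list(self.obs_ids),
            coords=None if self.coords is None else self.coords.copy(),
            labels=None if self.labels is None else list(self.labels),
        )

    def subset_obs(self, rows: Sequence[int]) -> "SpatialDataset":
        """Row-subset by integer positions (in the given order)."""
        rows = list(rows)
        expr = self.expr[rows, :] if not sp.issparse(self.expr) else self.expr.tocsr()[rows, :]
        return SpatialDataset(
            expr=expr,
            gene_ids=list(self.gene_ids),
            obs_ids=[self.obs_ids[i] for i in rows],
            coords=None if self.coords is None else self.coords[rows],
            labels=None if self.labels is None else [self.labels[i] for i in rows],
        )

    def copy(self) -> "SpatialDataset":
        expr = self.expr.copy()
        return SpatialDataset(
            expr=expr,
            gene_ids=list(self.gene_ids),
            obs_ids=list(self.obs_ids),
            coords=None if self.coords is None else self.coords.copy(),
            labels=None if self.labels is None else list(self.labels),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

Format = Literal["delimited", "mtx", "h5ad"]


def read_dataset(
    path: str | Path,
    format: Format = "delimited",
    coords_path: str | Path | None = None,
) -> SpatialDataset:
    """Read an expression dataset from one of the supported layouts.

    ``delimited``
        ``path`` is a counts table: header row of gene ids, first column of
        observation ids, observations x genes.  ``coords_path`` optionally
        names a 2- or 3-column coordinate table keyed by observation id.
    ``mtx``
        ``path`` is a directory holding the standard single-cell triplet
        layout ``matrix.mtx`` (features x barcodes), ``features.tsv``,
        ``barcodes.tsv`` and optionally ``coords.tsv``.
    ``h5ad``
        ``path`` is an HDF5-backed single-cell container; coordinates are
        taken from the observation-aligned 2D slot named ``"spatial"``
        when present.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such path: {path}")
    if format == "delimited":
        return _read_delimited(path, coords_path)
    if format == "mtx":
        return _read_mtx(path)
    if format == "h5ad":
        return _read_h5ad(path)
    raise ValidationError(f"unknown format: {format!r}")


def _read_delimited(path: Path, coords_path: str | Path | None) -> SpatialDataset:
    # pick up the sidecar write_dataset produces unless told otherwise
    default_sidecar = Path(str(path) + ".coords.tsv")
    if coords_path is None and default_sidecar.exists():
        coords_path = default_sidecar
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse delimited table {path}: {exc}") from exc
    # pandas mangles duplicate header fields (g, g.1, ...); check the raw header
    raw_header = pd.read_csv(
        path, sep=None, engine="python", header=None, nrows=1
    ).iloc[0, 1:]
    if raw_header.duplicated().any():
        dupes = sorted(raw_header[raw_header.duplicated()].astype(str).unique())
        raise ValidationError(f"duplicate gene ids in {path}: {dupes[:10]}")
    coords = None
    obs_ids = [str(x) for x in df.index]
    if coords_path is not None:
        cdf = pd.read_csv(coords_path, sep=None, engine="python", index_col=0)
        if cdf.shape[1] not in (2, 3):
            raise ParseError(
                f"coordinate table {coords_path} has {cdf.shape[1]} columns; expected 2 or 3"
            )
        missing = [o for o in obs_ids if o not in set(map(str, cdf.index))]
        if missing:
            raise ParseError(
                f"coordinate table {coords_path} missing observations: {missing[:10]}"
            )
        cdf.index = cdf.index.map(str)
        coords = cdf.loc[obs_ids].to_numpy(dtype=np.float64)
    return SpatialDataset(
        expr=df.to_numpy(dtype=np.float64),
        gene_ids=[str(c) for c in df.columns],
        obs_ids=obs_ids,
        coords=coords,
    )


def _read_mtx(path: Path) -> SpatialDataset:
    import scipy.io

    if not path.is_dir():
        raise ParseError(f"mtx format expects a directory, got {path}")
    mtx_file = path / "matrix.mtx"
    feat_file = path / "features.tsv"
    bc_file = path / "barcodes.tsv"
    for f in (mtx_file, feat_file, bc_file):
        if not f.exists():
            raise ParseError(f"mtx layout missing {f.name} in {path}")
    try:
        mat = scipy.io.mmread(mtx_file)  # features x barcodes
    except Exception as exc:
        raise ParseError(f"cannot parse {mtx_file}: {exc}") from exc
    gene_ids = feat_file.read_text().split()
    obs_ids = bc_file.read_text().split()
    expr = sp.csr_matrix(mat.T, dtype=np.float64)  # observations x genes
    coords = None
    coords_file = path / "coords.tsv"
    if coords_file.exists():
        cdf = pd.read_csv(coords_file, sep="\t", index_col=0)
        cdf.index = cdf.index.map(str)
        coords = cdf.loc[[str(o) for o in obs_ids]].to_numpy(dtype=np.float64)
    return SpatialDataset(expr=expr, gene_ids=gene_ids, obs_ids=obs_ids, coords=coords)


def _read_h5ad(path: Path) -> SpatialDataset:
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:
        raise ParseError(f"cannot read h5ad container {path}: {exc}") from exc
    coords = None
    if "spatial" in adata.obsm:
        coords = np.asarray(adata.obsm["spatial"], dtype=np.float64)
    labels = None
    if "label" in adata.obs.columns:
        labels = [str(x) for x in adata.obs["label"]]
    X = adata.X
    expr = sp.csr_matrix(X, dtype=np.float64) if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    return SpatialDataset(
        expr=expr,
        gene_ids=[str(g) for g in adata.var_names],
        obs_ids=[str(o) for o in adata.obs_names],
        coords=coords,
        labels=labels,
    )


def write_dataset(
    dataset: SpatialDataset,
    path: str | Path,
    format: Format = "delimited",
    coords_path: str | Path | None = None,
) -> None:
    """Write ``dataset`` in one of the supported layouts (see read_dataset)."""
    path = Path(path)
    if format == "delimited":
        df = pd.DataFrame(
            dataset.dense_expr(), index=dataset.obs_ids, columns=dataset.gene_ids
        )
        df.to_csv(path, sep="\t")
        if dataset.coords is not None:
            if coords_path is None:
                coords_path = Path(str(path) + ".coords.tsv")
            axes = ["x", "y", "z"][: dataset.coords.shape[1]]
            pd.DataFrame(dataset.coords, index=dataset.obs_ids, columns=axes).to_csv(
                coords_path, sep="\t"
            )
    elif format == "mtx":
        import scipy.io

        path.mkdir(parents=True, exist_ok=True)
        mat = sp.coo_matrix(dataset.expr).T  # features x barcodes
        scipy.io.mmwrite(str(path / "matrix.mtx"), mat)
        (path / "features.tsv").write_text("\n".join(dataset.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(dataset.obs_ids) + "\n")
        if dataset.coords is not None:
            axes = ["x", "y", "z"][: dataset.coords.shape[1]]
            pd.DataFrame(
                dataset.coords, index=dataset.obs_ids, columns=axes
            ).to_csv(path / "coords.tsv", sep="\t")
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=dataset.expr.copy(),
            obs=pd.DataFrame(index=dataset.obs_ids),
            var=pd.DataFrame(index=dataset.gene_ids),
        )
        if dataset.coords is not None:
            adata.obsm["spatial"] = dataset.coords.copy()
        if dataset.labels is not None:
            adata.obs["label"] = dataset.labels
        adata.write_h5ad(path)
    else:
        raise ValidationError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Coordinate normalization
# ---------------------------------------------------------------------------

_EPS_RANGE = 1e-12


@dataclass
class CoordNormalizer:
    """Per-axis min-max normalizer, Cartesian or polar.

    In polar mode the fitted points are first converted to
    (radius, angle in radians, angle in (-pi, pi]) about ``polar_center``
    (the centroid of the fitted points), and min-max is applied uniformly
    to both derived axes.
    """

    system: Literal["cartesian", "polar"]
    mins: np.ndarray = field(default_factory=lambda: np.zeros(0))
    maxs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    polar_center: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return len(self.mins)

    # raw coords -> internal axes (identity for cartesian)
    def _to_internal(self, coords: np.ndarray) -> np.ndarray:
        if self.system == "cartesian":
            return coords
        dx = coords[:, 0] - self.polar_center[0]
        dy = coords[:, 1] - self.polar_center[1]
        return np.column_stack([np.hypot(dx, dy), np.arctan2(dy, dx)])

    def _from_internal(self, internal: np.ndarray) -> np.ndarray:
        if self.system == "cartesian":
            return internal
        r, theta = internal[:, 0], internal[:, 1]
        return np.column_stack(
            [
                self.polar_center[0] + r * np.cos(theta),
                self.polar_center[1] + r * np.sin(theta),
            ]
        )

    def normalize(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != (
            2 if self.system == "polar" else self.dim
        ):
            raise ValidationError(
                f"expected (n, {self.dim}) coordinates, got {coords.shape}"
            )
        internal = self._to_internal(coords)
        return (internal - self.mins) / (self.maxs - self.mins)

    def denormalize(self, unit_coords: np.ndarray) -> np.ndarray:
        unit_coords = np.asarray(unit_coords, dtype=np.float64)
        if unit_coords.ndim != 2 or unit_coords.shape[1] != self.dim:
            raise ValidationError(
                f"expected (n, {self.dim}) unit coordinates, got {unit_coords.shape}"
            )
        internal = unit_coords * (self.maxs - self.mins) + self.mins
        return self._from_internal(internal)


def fit_coord_normalizer(
    coords: np.ndarray, system: Literal["cartesian", "polar"] = "cartesian"
) -> CoordNormalizer:
    """Fit per-axis min-max parameters on ``coords``.

    Polar mode (2D only) converts to (radius, angle) about the centroid
    before fitting; an axis with zero range — all points at one x, or all
    on one circle about the centroid — raises
    :class:`DegenerateGeometryError`.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need a (n>=2, d) coordinate matrix")
    if system == "polar":
        if coords.shape[1] != 2:
            raise ValidationError("polar normalization requires 2D coordinates")
        center = coords.mean(axis=0)
        norm = CoordNormalizer(system="polar", polar_center=center)
        internal = norm._to_internal(coords)
    elif system == "cartesian":
        norm = CoordNormalizer(system="cartesian")
        internal = coords
    else:
        raise ValidationError(f"unknown coordinate system: {system!r}")
    mins = internal.min(axis=0)
    maxs = internal.max(axis=0)
    degenerate = np.nonzero(maxs - mins <= _EPS_RANGE)[0]
    if degenerate.size:
        axis_names = (
            ["radius", "angle"]
            if system == "polar"
            else [f"axis {i}" for i in range(internal.shape[1])]
        )
        raise DegenerateGeometryError(
            "zero coordinate range on: "
            + ", ".join(axis_names[i] for i in degenerate)
        )
    norm.mins = mins
    norm.maxs = maxs
    return norm


def normalize_coords(coords: np.ndarray, normalizer: CoordNormalizer) -> np.ndarray:
    """Map raw coordinates to unit-interval targets (no clipping)."""
    return normalizer.normalize(coords)


def denormalize_coords(unit_coords: np.ndarray, normalizer: CoordNormalizer) -> np.ndarray:
    """Inverse of :func:`normalize_coords`."""
    return normalizer.denormalize(unit_coords)
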