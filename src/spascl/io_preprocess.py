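"""Loading, filtering, normalisation and graph construction for ST data.

The dataset container keeps expression as a gene-by-spot matrix
``X (d x n)``; spots are columns throughout the package.  The spot graph
blends a spatial k-nearest-neighbour graph ``A_S`` with an expression
k-nearest-neighbour graph ``A_E``:

    A = (1 - alpha) * A_S + alpha * A_E,   alpha in [0, 1].

Spatial neighbours capture contiguous tissue domains; expression
neighbours let spatially discontinuous domains share edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "STDataset",
    "AdjacencyPair",
    "load_dataset",
    "filter_named",
    "select_hvg",
    "normalize_log",
    "knn_adjacency",
    "blend_adjacency",
    "build_graph",
]


class AlignmentError(ValueError):
    """Spot ordering/counts disagree between expression, coords or labels."""


class FormatError(ValueError):
    """Unrecognised or unparsable input file."""


@dataclass
class STDataset:
    """A spatial transcriptomics section: genes x spots plus coordinates.

    Attributes
    ----------
    counts : (d, n) array
        Non-negative expression, genes in rows, spots in columns.
    gene_ids, spot_ids : unique identifier lists of length d and n.
    coords : (n, 2) array of spot positions (pixels or array units).
    image : optional 2D/3D pixel array (histology).
    ref_labels : optional per-spot reference annotation.
    meta : provenance of processing steps (normalisation, HVG statistic).
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    image: np.ndarray | None = None
    ref_labels: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        d, n = self.counts.shape
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != d:
            raise AlignmentError(f"{len(self.gene_ids)} gene ids for {d} genes")
        if len(self.spot_ids) != n or self.coords.shape[0] != n:
            raise AlignmentError(
                f"spot ids ({len(self.spot_ids)}) / coords rows "
                f"({self.coords.shape[0]}) do not match {n} matrix columns"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids must be unique")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids must be unique")
        if self.ref_labels is not None and len(self.ref_labels) != n:
            raise AlignmentError("ref_labels length does not match spot count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]


@dataclass
class AdjacencyPair:
    """Spatial, expression and blended spot-spot adjacency matrices."""

    A_spatial: np.ndarray
    A_expr: np.ndarray
    A_blend: np.ndarray
    alpha: float
    k_spatial: int
    k_expr: int


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Read gene-by-spot expression from MTX / CSV / h5ad.

    Returns (counts, gene_ids, spot_ids); ids are None when the format
    does not carry them (MTX without sidecar TSVs).
    """
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        counts = np.asarray(mmread(str(path)).todense(), dtype=np.float64)
        genes = barcodes = None
        gpath = path.with_name("genes.tsv")
        bpath = path.with_name("barcodes.tsv")
        if gpath.exists():
            genes = pd.read_csv(gpath, sep="\t", header=None)[0].astype(str).tolist()
        if bpath.exists():
            barcodes = pd.read_csv(bpath, sep="\t", header=None)[0].astype(str).tolist()
        return counts, genes, barcodes
    if suffix in (".csv", ".tsv"):
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return df.to_numpy(dtype=np.float64), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    if suffix in (".h5ad", ".h5"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        # AnnData is spots x genes; transpose to genes x spots
        return (
            np.asarray(X, dtype=np.float64).T,
            adata.var_names.astype(str).tolist(),
            adata.obs_names.astype(str).tolist(),
        )
    raise FormatError(f"unsupported expression format: {path}")


def load_dataset(
    matrix_path,
    coords_path,
    image_path=None,
    labels_path=None,
) -> STDataset:
    """Load an ST section from disk and align spots across inputs.

    The coordinates table needs columns ``spot_id,x,y`` (or the first
    three columns are taken in that order); labels need ``spot_id,label``.
    When the matrix carries spot identifiers, coords and labels are
    reindexed to the matrix ordering; otherwise row order must agree.
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    counts, gene_ids, spot_ids = _read_matrix(matrix_path)
    d, n = counts.shape
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(d)]

    cdf = pd.read_csv(coords_path)
    cols = {c.lower(): c for c in cdf.columns}
    if {"spot_id", "x", "y"} <= set(cols):
        cdf = cdf.set_index(cols["spot_id"])[[cols["x"], cols["y"]]]
    else:
        cdf = cdf.set_index(cdf.columns[0])
        cdf = cdf.iloc[:, :2]
    cdf.index = cdf.index.astype(str)
    if cdf.shape[0] != n:
        raise AlignmentError(
            f"coords has {cdf.shape[0]} rows for {n} matrix columns"
        )
    if spot_ids is None:
        spot_ids = cdf.index.tolist()
    else:
        if set(cdf.index) != set(spot_ids):
            raise AlignmentError("coords spot ids do not match matrix spot ids")
        cdf = cdf.loc[spot_ids]
    coords = cdf.to_numpy(dtype=np.float64)

    image = None
    if image_path is not None:
        from PIL import Image

        image = np.asarray(Image.open(image_path))

    ref_labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path)
        ldf = ldf.set_index(ldf.columns[0])
        ldf.index = ldf.index.astype(str)
        if ldf.shape[0] != n:
            raise AlignmentError(
                f"labels has {ldf.shape[0]} rows for {n} spots"
            )
        if set(ldf.index) != set(spot_ids):
            raise AlignmentError("label spot ids do not match matrix spot ids")
        ref_labels = ldf.loc[spot_ids].iloc[:, 0].tolist()

    return STDataset(counts, gene_ids, list(map(str, spot_ids)), coords,
                     image=image, ref_labels=ref_labels)


def filter_named(
    ds: STDataset,
    gene_patterns: list[str] = (),
    cell_label_exclusions: list = (),
) -> STDataset:
    """Drop genes by name pattern and spots by reference label.

    Patterns ending in ``*`` are prefix rules (``"Blank*"`` removes every
    gene whose name starts with ``Blank``, the blank-probe convention of
    imaging-based platforms); all other patterns are exact names.
    Ordering of the survivors is preserved.
    """
    prefixes = tuple(p[:-1] for p in gene_patterns if p.endswith("*"))
    exact = {p for p in gene_patterns if not p.endswith("*")}

    def drop(g: str) -> bool:
        return g in exact or (bool(prefixes) and g.startswith(prefixes))

    gene_keep = np.array([not drop(g) for g in ds.gene_ids], dtype=bool)
    if not gene_keep.any():
        raise ValueError("gene filtering removed every gene")

    spot_keep = np.ones(ds.n_spots, dtype=bool)
    if cell_label_exclusions and ds.ref_labels is not None:
        excl = set(cell_label_exclusions)
        spot_keep = np.array([lab not in excl for lab in ds.ref_labels], dtype=bool)

    return STDataset(
        ds.counts[np.ix_(gene_keep, spot_keep)],
        [g for g, k in zip(ds.gene_ids, gene_keep) if k],
        [s for s, k in zip(ds.spot_ids, spot_keep) if k],
        ds.coords[spot_keep],
        image=ds.image,
        ref_labels=(
            [l for l, k in zip(ds.ref_labels, spot_keep) if k]
            if ds.ref_labels is not None else None
        ),
        meta=dict(ds.meta),
    )


def select_hvg(ds: STDataset, n_top: int = 3000) -> STDataset:
    """Keep the ``n_top`` most highly variable genes.

    Ranking uses Seurat-style normalised dispersion (scanpy
    ``flavor="seurat"`` on log-normalised expression): genes are binned
    by mean and dispersion is z-scored within bins, so highly expressed
    genes do not dominate.  Panels already at or below ``n_top`` genes
    are returned unchanged (targeted platforms measure few genes and
    need no selection).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if ds.n_genes <= n_top:
        return ds

    import scanpy as sc
    from anndata import AnnData

    adata = AnnData(ds.counts.T.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    order = np.argsort(-adata.var["dispersions_norm"].to_numpy(), kind="stable")
    keep_idx = np.sort(order[:n_top])

    out = replace(
        ds,
        counts=ds.counts[keep_idx],
        gene_ids=[ds.gene_ids[i] for i in keep_idx],
        meta={**ds.meta, "hvg_statistic": "seurat_normalized_dispersion",
              "hvg_n_top": int(n_top)},
    )
    return out


def normalize_log(
    ds: STDataset,
    target_sum: float = 1e4,
    zero_spots: str = "drop",
) -> STDataset:
    """Library-size normalise each spot to ``target_sum`` then log1p.

    ``zero_spots`` controls spots with zero total counts, whose scale is
    undefined: ``"drop"`` removes them with a warning, ``"keep"`` leaves
    them at zero, ``"error"`` raises.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    sums = ds.counts.sum(axis=0)
    zero = sums == 0
    if zero.any():
        if zero_spots == "error":
            raise ValueError(f"{int(zero.sum())} spots have zero total counts")
        logger.warning("%d spots have zero total counts (%s)",
                       int(zero.sum()), zero_spots)
    if zero_spots == "drop" and zero.any():
        keep = ~zero
        ds = replace(
            ds,
            counts=ds.counts[:, keep],
            spot_ids=[s for s, k in zip(ds.spot_ids, keep) if k],
            coords=ds.coords[keep],
            ref_labels=(
                [l for l, k in zip(ds.ref_labels, keep) if k]
                if ds.ref_labels is not None else None
            ),
        )
        sums = sums[keep]
        zero = sums == 0
    scale = np.divide(target_sum, sums, out=np.zeros_like(sums), where=sums > 0)
    X = np.log1p(ds.counts * scale[None, :])
    return replace(ds, counts=X,
                   meta={**ds.meta, "normalized": True,
                         "target_sum": float(target_sum)})


def knn_adjacency(points: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """Binary symmetric k-nearest-neighbour adjacency of point rows.

    Each point selects its k nearest others (self excluded, distance ties
    broken toward the lower index); the graph is symmetrised by union, so
    every selected neighbour keeps its edge.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = cdist(points, points, metric=metric)
    np.fill_diagonal(D, np.inf)
    # stable argsort: equidistant neighbours resolve to the lower index
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, idx.ravel()] = 1.0
    A = np.maximum(A, A.T)  # union symmetrisation
    np.fill_diagonal(A, 0.0)
    return A


def blend_adjacency(A_S: np.ndarray, A_E: np.ndarray, alpha: float,
                    k_spatial: int = 0, k_expr: int = 0) -> AdjacencyPair:
    """Blend spatial and expression graphs: A = (1-alpha) A_S + alpha A_E."""
    A_S = np.asarray(A_S, dtype=np.float64)
    A_E = np.asarray(A_E, dtype=np.float64)
    if A_S.shape != A_E.shape:
        raise ValueError("adjacency shape mismatch")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    A = (1.0 - alpha) * A_S + alpha * A_E
    return AdjacencyPair(A_S, A_E, A, float(alpha), int(k_spatial), int(k_expr))


def build_graph(ds: STDataset, k_spatial: int = 10, k_expr: int = 10,
                alpha: float = 0.5) -> AdjacencyPair:
    """Convenience: kNN graphs on coords and expression, then blend."""
    A_S = knn_adjacency(ds.coords, k_spatial)
    A_E = knn_adjacency(ds.counts.T, k_expr)
    return blend_adjacency(A_S, A_E, alpha, k_spatial, k_expr)
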