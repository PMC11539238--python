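"""Synthetic spatial-transcriptomics fixtures with planted structure.

Two generators cover the two statistical assumptions the pipeline
relies on:

* ``generate_grid_st`` — spots on a regular 2D grid partitioned into K
  contiguous domains (horizontal bands or rectangular blocks).  Each
  domain has a set of marker genes whose log-mean is shifted by
  ``effect_size``; counts are log-normal-like (Gaussian in log space,
  exponentiated and rounded), so library-size normalisation and log
  transform are exercised realistically.  Optional morphology features
  are a noisy one-hot domain code, standing in for image-patch
  embeddings without rendering an image.

* ``generate_union_subspaces`` — points drawn from a union of random
  low-dimensional linear subspaces, the setting in which self-expression
  provably concentrates coefficients within subspaces.

What these fixtures do not emulate: zero inflation, spot-swapping
bleed, platform-specific count depth profiles, or real histology
texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import MorphologyFeatures
from .io_preprocess import STDataset

__all__ = ["SyntheticSpec", "generate_grid_st", "generate_union_subspaces"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-domain grid generator."""

    grid: tuple[int, int] = (20, 30)
    n_domains: int = 3
    layout: str = "bands"
    n_genes: int = 50
    markers_per_domain: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    base_log_mean: float = 2.0
    morphology_dim: int = 8
    morphology_effect: float = 3.0
    morphology_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid
        if self.n_domains > rows * cols:
            raise ValueError("more domains than spots")
        if self.layout == "bands" and self.n_domains > rows:
            raise ValueError("bands layout needs n_domains <= rows")
        if self.layout not in ("bands", "blocks"):
            raise ValueError(f"unknown layout: {self.layout!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _domain_labels(spec: SyntheticSpec) -> np.ndarray:
    rows, cols = spec.grid
    K = spec.n_domains
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.layout == "bands":
        # horizontal bands of near-equal height
        lab = np.minimum(rr * K // rows, K - 1)
    else:
        # blocks: split rows into ceil(sqrt(K)) strips, fill along columns
        n_strips = int(np.ceil(np.sqrt(K)))
        strip = np.minimum(rr * n_strips // rows, n_strips - 1)
        per_strip = int(np.ceil(K / n_strips))
        within = np.minimum(cc * per_strip // cols, per_strip - 1)
        lab = np.minimum(strip * per_strip + within, K - 1)
    return lab.ravel()


def generate_grid_st(
    spec: SyntheticSpec,
) -> tuple[STDataset, np.ndarray, MorphologyFeatures]:
    """Generate a planted-domain grid section.

    Returns the dataset (gene-by-spot counts, integer grid coordinates,
    reference labels attached), the label vector, and per-spot morphology
    features correlated with the domain.  Deterministic in the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    n = rows * cols
    labels = _domain_labels(spec)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(np.float64)

    # disjoint marker sets, one per domain
    K = spec.n_domains
    d = spec.n_genes
    if K * spec.markers_per_domain > d:
        raise ValueError("marker sets exceed the gene panel")
    marker_idx = rng.permutation(d)[: K * spec.markers_per_domain]
    log_mu = np.full((d, n), spec.base_log_mean)
    for k in range(K):
        genes = marker_idx[k * spec.markers_per_domain:(k + 1) * spec.markers_per_domain]
        log_mu[np.ix_(genes, np.flatnonzero(labels == k))] += spec.effect_size

    log_expr = log_mu + rng.normal(0.0, spec.noise_sd, size=(d, n))
    counts = np.round(np.exp(log_expr)).astype(np.float64)

    ds = STDataset(
        counts,
        [f"gene_{i}" for i in range(d)],
        [f"spot_{i}" for i in range(n)],
        coords,
        ref_labels=labels.tolist(),
        meta={"synthetic": True, "layout": spec.layout, "seed": spec.seed},
    )

    one_hot = np.zeros((n, spec.morphology_dim))
    one_hot[np.arange(n), labels % spec.morphology_dim] = spec.morphology_effect
    X_I = one_hot + rng.normal(0.0, spec.morphology_noise_sd,
                               size=(n, spec.morphology_dim))
    feats = MorphologyFeatures(X_I, extractor_id="synthetic_onehot")
    return ds, labels, feats


def generate_union_subspaces(
    n_per: int,
    subspace_dim: int,
    ambient_dim: int,
    n_subspaces: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    orthogonal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points from a union of random linear subspaces.

    Each class draws ``n_per`` points as a random orthonormal basis of a
    ``subspace_dim``-dimensional subspace times standard-normal
    coefficients, plus isotropic ambient noise.  With ``orthogonal`` the
    class subspaces are mutually orthogonal (requires
    ``n_subspaces * subspace_dim <= ambient_dim``), which makes the
    linear-kernel Gram matrix exactly block diagonal at zero noise.
    Returns the (ambient_dim, n_per * n_subspaces) point matrix (points
    as columns) and integer class labels.
    """
    if subspace_dim >= ambient_dim:
        raise ValueError("subspace_dim must be smaller than ambient_dim")
    rng = np.random.default_rng(seed)
    bases = None
    if orthogonal:
        total = n_subspaces * subspace_dim
        if total > ambient_dim:
            raise ValueError("orthogonal subspaces need "
                             "n_subspaces * subspace_dim <= ambient_dim")
        Q_all, _ = np.linalg.qr(rng.standard_normal((ambient_dim, total)))
        bases = [Q_all[:, k * subspace_dim:(k + 1) * subspace_dim]
                 for k in range(n_subspaces)]
    cols, labels = [], []
    for k in range(n_subspaces):
        if bases is not None:
            Q = bases[k]
        else:
            G = rng.standard_normal((ambient_dim, subspace_dim))
            Q, _ = np.linalg.qr(G)
        coeff = rng.standard_normal((subspace_dim, n_per))
        pts = Q @ coeff
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
        cols.append(pts)
        labels.extend([k] * n_per)
    return np.hstack(cols), np.asarray(labels)
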