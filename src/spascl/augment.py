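"""Graph augmentation: positive views, morphology prior, corrupted negative.

Contrastive training needs two positive views of the spot graph and one
negative.  The first positive view masks a random subset of gene
dimensions.  The second perturbs edges; when a histology image (or
precomputed morphology features) is available the perturbation is guided
by a morphology k-nearest-neighbour graph ``A_I``:

    tau_A(A) = A ⊙ (1 − L ⊙ (A − A ⊙ A_I)) + (1 − A) ⊙ (L ⊙ (A_I − A ⊙ A_I))

with ⊙ the elementwise product and ``L`` a symmetric random location
matrix.  The first term drops edges the morphology graph does not
support; the second adds edges between morphologically similar but
unconnected spots.  Entries where ``A`` and ``A_I`` agree are provably
untouched.  The negative view shuffles spot profiles, keeping the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import knn_adjacency

__all__ = [
    "MorphologyFeatures",
    "PerturbationMask",
    "ViewBundle",
    "tile_and_embed",
    "morphology_knn",
    "sample_mask_L",
    "edge_perturb_prior",
    "random_edge_perturb",
    "attribute_mask",
    "shuffle_negative",
    "make_extractor",
    "build_views",
]


@dataclass
class MorphologyFeatures:
    """Per-spot image-patch embeddings, one row per spot."""

    X_I: np.ndarray
    extractor_id: str

    def __post_init__(self):
        self.X_I = np.asarray(self.X_I, dtype=np.float64)
        if not np.all(np.isfinite(self.X_I)):
            raise ValueError("morphology features must be finite")


@dataclass
class PerturbationMask:
    """Symmetric binary matrix flagging the perturbed spot pairs."""

    L: np.ndarray
    rate: float
    seed: int


@dataclass
class ViewBundle:
    """Original graph, two positive views and the corrupted negative."""

    X: np.ndarray
    A: np.ndarray
    X1_pos: np.ndarray
    A1_pos: np.ndarray
    X2_pos: np.ndarray
    A2_pos: np.ndarray
    X_neg: np.ndarray
    A_neg: np.ndarray
    A_I: np.ndarray | None = None


def _check_sym_binary(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if not np.array_equal(A, A.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary")
    if np.any(np.diag(A) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return A


# ---------------------------------------------------------------------------
# morphology features


def make_extractor(kind: str, out_dim: int = 64, seed: int = 0):
    """Build a patch -> vector feature extractor.

    ``pixel_mean`` averages pixel values per channel; ``random_projection``
    applies a fixed seeded Gaussian projection of the flattened patch.
    Any callable mapping a patch array to a 1-D vector also works as an
    extractor (e.g. a CNN penultimate layer supplied by the user).
    """
    if kind == "pixel_mean":
        def extract(patch: np.ndarray) -> np.ndarray:
            p = np.asarray(patch, dtype=np.float64)
            if p.ndim == 2:
                return np.array([p.mean()])
            return p.reshape(-1, p.shape[-1]).mean(axis=0)

        return extract
    if kind == "random_projection":
        rng = np.random.default_rng(seed)
        W: dict[int, np.ndarray] = {}

        def extract(patch: np.ndarray) -> np.ndarray:
            v = np.asarray(patch, dtype=np.float64).ravel()
            if v.size not in W:
                # one fixed projection per input size, derived from the seed
                r = np.random.default_rng(seed + v.size)
                W[v.size] = r.standard_normal((out_dim, v.size)) / np.sqrt(v.size)
            return W[v.size] @ v

        return extract
    raise ValueError(f"unknown extractor kind: {kind!r}")


def _crop_patch(image: np.ndarray, cx: float, cy: float, size: int) -> np.ndarray:
    """Square patch centred on (x, y) pixel coords, zero-padded at edges."""
    h, w = image.shape[:2]
    half = size // 2
    x0, y0 = int(round(cx)) - half, int(round(cy)) - half
    pad_shape = (size, size) + image.shape[2:]
    patch = np.zeros(pad_shape, dtype=np.float64)
    sy0, sy1 = max(y0, 0), min(y0 + size, h)
    sx0, sx1 = max(x0, 0), min(x0 + size, w)
    if sy1 > sy0 and sx1 > sx0:
        patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return patch


def tile_and_embed(
    image: np.ndarray,
    coords: np.ndarray,
    patch_size: int = 50,
    resize_to: int = 224,
    extractor=None,
    extractor_id: str = "pixel_mean",
    pad: bool = True,
) -> MorphologyFeatures:
    """Crop a patch around each spot, resize, and embed it.

    Coordinates are (x, y) in pixels.  Patches crossing the image border
    are zero-padded (``pad=False`` raises instead).  Each patch is resized
    to ``resize_to`` square before the extractor runs, so extractors see a
    fixed input size regardless of ``patch_size``.
    """
    image = np.asarray(image)
    coords = np.asarray(coords, dtype=np.float64)
    if extractor is None:
        extractor = make_extractor(extractor_id)
    h, w = image.shape[:2]
    half = patch_size // 2
    rows = []
    for cx, cy in coords:
        if not pad and (cx - half < 0 or cy - half < 0
                        or cx + half > w or cy + half > h):
            raise ValueError(f"spot at ({cx}, {cy}) falls outside the image")
        patch = _crop_patch(image, cx, cy, patch_size)
        if resize_to and resize_to != patch_size:
            patch = _resize(patch, resize_to)
        rows.append(np.asarray(extractor(patch), dtype=np.float64).ravel())
    return MorphologyFeatures(np.vstack(rows), extractor_id)


def _resize(patch: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    arr = patch
    scale = 255.0 / arr.max() if arr.max() > 0 else 1.0
    img = Image.fromarray((arr * scale).astype(np.uint8))
    out = np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.float64)
    return out / scale


def morphology_knn(feats: MorphologyFeatures, k: int) -> np.ndarray:
    """Morphology kNN graph A_I over per-spot feature rows."""
    return knn_adjacency(feats.X_I, k)


# ---------------------------------------------------------------------------
# edge perturbation


def sample_mask_L(n: int, A_bin: np.ndarray, A_I: np.ndarray,
                  rate: float, seed: int) -> PerturbationMask:
    """Sample the symmetric perturbation location matrix L.

    Only spot pairs where the graph and the morphology graph disagree can
    change under the prior-guided perturbation, so L is supported on the
    disagreement set; each pair (i < j) is flagged independently with
    probability ``rate``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    A_bin = _check_sym_binary(A_bin, "A_bin")
    A_I = _check_sym_binary(A_I, "A_I")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    disagree = (A_bin[iu] != A_I[iu])
    flags = (rng.random(iu[0].size) < rate) & disagree
    L = np.zeros((n, n))
    L[iu] = flags.astype(np.float64)
    L = L + L.T
    return PerturbationMask(L, float(rate), int(seed))


def edge_perturb_prior(A_bin: np.ndarray, A_I: np.ndarray,
                       L: PerturbationMask | np.ndarray) -> np.ndarray:
    """Morphology-prior edge perturbation tau_A(A).

    Flagged edges absent from A_I are dropped; flagged non-edges present
    in A_I are added.  At L = 0 the graph is unchanged; at L = all-ones
    the result is exactly A_I.
    """
    Lm = L.L if isinstance(L, PerturbationMask) else np.asarray(L, dtype=np.float64)
    A = _check_sym_binary(A_bin, "A_bin")
    AI = _check_sym_binary(A_I, "A_I")
    if A.shape != AI.shape or A.shape != Lm.shape:
        raise ValueError("shape mismatch between A, A_I and L")
    keep = A * (1.0 - Lm * (A - A * AI))
    add = (1.0 - A) * (Lm * (AI - A * AI))
    out = keep + add
    np.fill_diagonal(out, 0.0)
    return out


def random_edge_perturb(A_bin: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Domain-agnostic edge perturbation: drop and add edges at random.

    Each existing edge is dropped with probability ``rate``; the same
    number of currently absent pairs are connected, keeping the expected
    edge count.  Output is symmetric with zero diagonal.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    A = _check_sym_binary(A_bin, "A_bin")
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    upper = A[iu].astype(bool)
    drop = upper & (rng.random(iu[0].size) < rate)
    n_drop = int(drop.sum())
    non_edges = np.flatnonzero(~upper)
    add = np.zeros(iu[0].size, dtype=bool)
    if n_drop > 0 and non_edges.size > 0:
        chosen = rng.choice(non_edges, size=min(n_drop, non_edges.size),
                            replace=False)
        add[chosen] = True
    new_upper = (upper & ~drop) | add
    out = np.zeros((n, n))
    out[iu] = new_upper.astype(np.float64)
    return out + out.T


# ---------------------------------------------------------------------------
# node masking and corruption


def attribute_mask(X: np.ndarray, mask_rate: float, seed: int) -> np.ndarray:
    """Zero a random fraction of gene dimensions across all spots."""
    if not 0.0 <= mask_rate <= 1.0:
        raise ValueError("mask_rate must lie in [0, 1]")
    X = np.asarray(X, dtype=np.float64)
    d = X.shape[0]
    n_mask = int(round(mask_rate * d))
    rng = np.random.default_rng(seed)
    masked = rng.choice(d, size=n_mask, replace=False)
    out = X.copy()
    out[masked, :] = 0.0
    return out


def shuffle_negative(X: np.ndarray, seed: int) -> np.ndarray:
    """Corrupt features by permuting spot columns (profiles preserved)."""
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[1])
    return X[:, perm]


def build_views(
    X: np.ndarray,
    A: np.ndarray,
    A_I: np.ndarray | None,
    mask_rate: float,
    edge_rate: float,
    seed: int,
    edge_aug: str = "HS_image",
) -> ViewBundle:
    """Assemble the contrastive views for one augmentation round.

    ``edge_aug="HS_image"`` uses the morphology-prior perturbation and
    needs ``A_I``; ``"edge"`` falls back to random drop/add.  The blended
    weighted graph is binarised (entry > 0) for augmentation since edge
    flips are defined on binary adjacencies; the negative view keeps the
    original graph and only shuffles features.
    """
    A = np.asarray(A, dtype=np.float64)
    A_bin = (A > 0).astype(np.float64)
    np.fill_diagonal(A_bin, 0.0)
    n = A.shape[0]
    X1 = attribute_mask(X, mask_rate, seed)
    if edge_aug == "HS_image":
        if A_I is None:
            raise ValueError("edge_aug='HS_image' requires a morphology graph A_I")
        L = sample_mask_L(n, A_bin, A_I, edge_rate, seed + 1)
        A2 = edge_perturb_prior(A_bin, A_I, L)
    elif edge_aug == "edge":
        A2 = random_edge_perturb(A_bin, edge_rate, seed + 1)
    else:
        raise ValueError(f"unknown edge augmentation: {edge_aug!r}")
    X_neg = shuffle_negative(X, seed + 2)
    return ViewBundle(X, A, X1, A, X, A2, X_neg, A, A_I=A_I)
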