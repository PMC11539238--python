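"""Clustering of the learned embedding and partition-agreement scores.

Two clustering routes mirror common ST practice: a Gaussian mixture with
full covariances at fixed K (model-based clustering), and Louvain
community detection on a kNN graph of the embedding with the resolution
bisected to hit a requested cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.mixture import GaussianMixture

from .io_preprocess import knn_adjacency

__all__ = ["ClusteringResult", "cluster_embedding", "ari", "nmi"]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    score_table: dict = field(default_factory=dict)


def _louvain(H: np.ndarray, target_k: int | None, resolution: float,
             knn: int, seed: int) -> tuple[np.ndarray, float]:
    import igraph as ig

    # cosine-like geometry: L2-normalise embedding columns before kNN
    cols = H / np.maximum(np.linalg.norm(H, axis=0, keepdims=True), 1e-12)
    A = knn_adjacency(cols.T, min(knn, cols.shape[1] - 1))
    src, dst = np.nonzero(np.triu(A))
    g = ig.Graph(n=A.shape[0], edges=list(zip(src.tolist(), dst.tolist())))

    import random as _pyrandom

    def run(res: float) -> np.ndarray:
        ig.set_random_number_generator(_pyrandom.Random(seed))
        part = g.community_multilevel(resolution=res)
        return np.asarray(part.membership)

    if target_k is None:
        return run(resolution), resolution
    lo, hi = 0.01, 10.0
    lab = run(resolution)
    if len(set(lab)) == target_k:
        return lab, resolution
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        lab = run(mid)
        k = len(set(lab))
        if k == target_k:
            return lab, mid
        if k < target_k:
            lo = mid
        else:
            hi = mid
    return lab, mid


def cluster_embedding(
    H: np.ndarray,
    method: str = "gmm",
    k_or_resolution=None,
    seed: int = 0,
    ref=None,
    knn: int = 15,
) -> ClusteringResult:
    """Cluster spot embeddings (columns of H).

    ``gmm``: full-covariance Gaussian mixture at fixed K, best of 10
    seeded restarts by likelihood.  ``louvain``: community detection on
    a kNN graph of L2-normalised embeddings; if ``k_or_resolution`` is an
    integer the resolution is bisected toward that cluster count,
    otherwise it is used as the resolution directly.  When reference
    labels are given, ARI and NMI are recorded in ``score_table``.
    """
    H = np.asarray(H, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValueError("embedding contains non-finite values")
    n = H.shape[1]
    if method == "gmm":
        K = int(k_or_resolution) if k_or_resolution is not None else 8
        if K > n:
            raise ValueError(f"K={K} exceeds the number of spots {n}")
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             n_init=10, random_state=seed)
        labels = gm.fit_predict(H.T)
        params = {"K": K, "seed": seed}
    elif method == "louvain":
        target_k = None
        resolution = 1.0
        if k_or_resolution is not None:
            if float(k_or_resolution).is_integer():
                target_k = int(k_or_resolution)
            else:
                resolution = float(k_or_resolution)
        labels, used_res = _louvain(H, target_k, resolution, knn, seed)
        params = {"resolution": used_res, "target_k": target_k, "knn": knn}
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    result = ClusteringResult(np.asarray(labels), method, params)
    if ref is not None:
        result.score_table = {"ARI": ari(labels, ref), "NMI": nmi(labels, ref)}
    return result


def ari(pred, ref) -> float:
    """Adjusted Rand index between two partitions of the same spots."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("label vectors must have equal length")
    return float(_skm.adjusted_rand_score(ref, pred))


def nmi(pred, ref) -> float:
    """Normalized mutual information (arithmetic-mean normalisation)."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("label vectors must have equal length")
    return float(_skm.normalized_mutual_info_score(ref, pred,
                                                   average_method="arithmetic"))
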