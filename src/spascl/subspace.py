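"""Kernel self-expression on the graph-propagated embedding.

Spots in one spatial domain are assumed to lie near a common low-
dimensional subspace of the latent space, so each spot can be written as
a linear combination of its co-domain peers.  The coefficient matrix C
minimises the ridge-regularised self-expression objective in a
reproducing-kernel feature space:

    min_C  1/2 || Phi(H) S C - Phi(H) ||_F^2  +  beta/2 ||C||_F^2,

with S the symmetrically normalised adjacency (graph propagation before
self-expression).  Setting the gradient to zero in kernel form gives the
closed-form global minimiser of this strictly convex problem:

    C = (S' K S + beta I)^{-1} S' K,        K = Phi(H)' Phi(H),

solved as an SPD linear system.  Keeping only the top-k coefficients per
column yields the co-domain neighbour matrix C* = M ⊙ C used both as
contrastive context (via Z = H_view C) and as a neighbour set for
label smoothing or network visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SelfExpression",
    "ReconstructedViews",
    "gram",
    "solve_self_expression",
    "selfexpress_objective",
    "topk_filter",
    "reconstruct_views",
    "neighbor_majority_label",
]


@dataclass
class SelfExpression:
    """Self-expression coefficients C, top-k filter M and C* = M ⊙ C."""

    C: np.ndarray
    M: np.ndarray
    C_star: np.ndarray
    beta: float
    kernel: str
    top_k: int


@dataclass
class ReconstructedViews:
    """Subspace-reconstructed contexts Z1 = H1 C, Z2 = H2 C."""

    Z1: np.ndarray
    Z2: np.ndarray


def gram(H: np.ndarray, kernel: str = "linear",
         gamma: float | None = None) -> np.ndarray:
    """Gram matrix of spot embeddings (columns of H).

    ``linear`` gives K = H'H; ``rbf`` gives K_ij = exp(-gamma ||h_i - h_j||^2)
    with gamma defaulting to the median heuristic (1 / median squared
    pairwise distance).
    """
    H = np.asarray(H, dtype=np.float64)
    if kernel == "linear":
        return H.T @ H
    if kernel == "rbf":
        sq = np.sum(H * H, axis=0)
        D2 = sq[:, None] + sq[None, :] - 2.0 * (H.T @ H)
        np.maximum(D2, 0.0, out=D2)
        if gamma is None:
            off = D2[~np.eye(D2.shape[0], dtype=bool)]
            med = np.median(off) if off.size else 1.0
            gamma = 1.0 / med if med > 0 else 1.0
        return np.exp(-gamma * D2)
    raise ValueError(f"unknown kernel: {kernel!r}")


def solve_self_expression(K: np.ndarray, S_hat: np.ndarray,
                          beta: float = 1.0) -> np.ndarray:
    """Closed-form minimiser C = (S'KS + beta I)^{-1} S'K.

    The system matrix is symmetric positive definite for beta > 0 and a
    PSD Gram matrix, so it is solved by a Cholesky-backed SPD solve; a
    small diagonal jitter retries once if the kernel is PSD only up to
    round-off.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    K = np.asarray(K, dtype=np.float64)
    S = np.asarray(S_hat, dtype=np.float64)
    n = K.shape[0]
    SK = S.T @ K
    lhs = SK @ S + beta * np.eye(n)
    lhs = 0.5 * (lhs + lhs.T)
    try:
        return scipy.linalg.solve(lhs, SK, assume_a="pos")
    except np.linalg.LinAlgError:
        return scipy.linalg.solve(lhs + 1e-8 * np.eye(n), SK, assume_a="pos")


def selfexpress_objective(C: np.ndarray, K: np.ndarray, S_hat: np.ndarray,
                          beta: float) -> float:
    """Value of the kernelised self-expression objective at C.

    Expands 1/2||Phi S C - Phi||_F^2 through the Gram matrix, so it is
    evaluable for implicit feature maps.
    """
    S = np.asarray(S_hat, dtype=np.float64)
    SC = S @ C
    fit = 0.5 * (np.trace(SC.T @ K @ SC) - 2.0 * np.trace(K @ SC) + np.trace(K))
    return float(fit + 0.5 * beta * np.sum(C * C))


def topk_filter(C: np.ndarray, top_k: int,
                use_magnitude: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-column top-k filter M and the filtered matrix C* = M ⊙ C.

    Ranks coefficient magnitudes |C| within each column — a spot's
    strongest self-expression weights can be negative, and dropping them
    would discard in-domain neighbours (set ``use_magnitude=False`` to
    rank signed values instead).  Ties resolve toward the smaller row
    index.  ``top_k >= n`` keeps everything.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    C = np.asarray(C, dtype=np.float64)
    n = C.shape[0]
    k = min(top_k, n)
    ranked = np.abs(C) if use_magnitude else C
    # stable argsort on the negated values: ties keep ascending row order
    order = np.argsort(-ranked, axis=0, kind="stable")[:k, :]
    M = np.zeros_like(C)
    cols = np.tile(np.arange(C.shape[1]), (k, 1))
    M[order, cols] = 1.0
    return M, M * C


def reconstruct_views(H1_pos: np.ndarray, H2_pos: np.ndarray,
                      C_used: np.ndarray) -> ReconstructedViews:
    """One-step linearisation: Z1 = H1 C, Z2 = H2 C.

    Column i of Z mixes view embeddings with spot i's self-expression
    weights, giving a per-spot co-domain context vector.
    """
    H1 = np.asarray(H1_pos, dtype=np.float64)
    H2 = np.asarray(H2_pos, dtype=np.float64)
    C = np.asarray(C_used, dtype=np.float64)
    if H1.shape != H2.shape or H1.shape[1] != C.shape[0]:
        raise ValueError("shape mismatch between views and C")
    return ReconstructedViews(H1 @ C, H2 @ C)


def neighbor_majority_label(C_star: np.ndarray, labels) -> list:
    """Relabel each spot by the modal label of its retained neighbours.

    Neighbours of spot j are the rows with nonzero filter weight in
    column j.  Ties, or an empty neighbour set, keep the spot's own
    label.
    """
    C_star = np.asarray(C_star)
    labels = list(labels)
    n = C_star.shape[0]
    if len(labels) != n:
        raise ValueError("labels must align with C* columns")
    out = []
    for j in range(n):
        nbr = np.flatnonzero(C_star[:, j] != 0)
        if nbr.size == 0:
            out.append(labels[j])
            continue
        vals, counts = np.unique([labels[i] for i in nbr], return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        if winners.size > 1:
            out.append(labels[j])
        else:
            out.append(winners[0].item() if hasattr(winners[0], "item") else winners[0])
    return out
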