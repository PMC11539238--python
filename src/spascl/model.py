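"""GCN encoder/decoder, readout, discriminator and the training losses.

The encoder is a graph convolution with symmetric normalisation and a
learnable PReLU:

    f(X, A) = PReLU(W_e X S),   S = D^{-1/2} (A + I) D^{-1/2},

acting on a gene-by-spot matrix ``X (d x n)`` so each column of
``H = f(X, A) (d' x n)`` is a spot embedding.  The decoder mirrors the
encoder.  Two bilinear discriminators score spot embeddings against
context vectors: global summaries of the two positive views
(local-global loss) or per-spot subspace reconstructions (local-subspace
loss).  Shuffled-feature embeddings serve as negatives.  The total
objective adds a Frobenius reconstruction term:

    L_total = L_global + lambda1 * L_subspace + lambda2 * L_recon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, clip, log, matmul, prelu, sigmoid

__all__ = [
    "ModelParams",
    "init_params",
    "sym_normalize",
    "encode",
    "decode",
    "readout",
    "discriminate",
    "loss_local_global",
    "loss_subspace",
    "loss_recon",
    "total_loss",
    "EPS",
]

#: probability clamp keeping log terms finite
EPS = 1e-7


@dataclass
class ModelParams:
    """Learnable parameters of the encoder, decoder and discriminators."""

    enc_weights: list
    enc_slopes: list
    dec_weights: list
    dec_slopes: list
    W_disc_global: Tensor
    W_disc_sub: Tensor
    hidden_dim: int
    n_layers: int
    meta: dict = field(default_factory=dict)

    def parameters(self) -> list:
        return (list(self.enc_weights) + list(self.enc_slopes)
                + list(self.dec_weights) + list(self.dec_slopes)
                + [self.W_disc_global, self.W_disc_sub])

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["shape_info"] = np.array([self.hidden_dim, self.n_layers])
        np.savez(path, **arrays)


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_out, fan_in))


def init_params(d: int, hidden_dim: int = 64, n_layers: int = 1,
                seed: int = 0) -> ModelParams:
    """Glorot-uniform initialisation; PReLU slopes start at 0.25.

    More than 3 graph-convolution layers over-smooths spot embeddings,
    so the depth is capped.
    """
    if not 1 <= n_layers <= 3:
        raise ValueError("n_layers must be between 1 and 3")
    rng = np.random.default_rng(seed)
    dims = [d] + [hidden_dim] * n_layers
    enc_w = [Tensor(_glorot(rng, dims[i + 1], dims[i]), requires_grad=True)
             for i in range(n_layers)]
    dec_dims = dims[::-1]
    dec_w = [Tensor(_glorot(rng, dec_dims[i + 1], dec_dims[i]), requires_grad=True)
             for i in range(n_layers)]
    enc_s = [Tensor(0.25, requires_grad=True) for _ in range(n_layers)]
    dec_s = [Tensor(0.25, requires_grad=True) for _ in range(n_layers)]
    Wg = Tensor(_glorot(rng, hidden_dim, hidden_dim), requires_grad=True)
    Ws = Tensor(_glorot(rng, hidden_dim, hidden_dim), requires_grad=True)
    return ModelParams(enc_w, enc_s, dec_w, dec_s, Wg, Ws, hidden_dim, n_layers)


def sym_normalize(A: np.ndarray) -> np.ndarray:
    """Symmetrically normalised adjacency with self-loops.

    Returns ``D^{-1/2} (A + I) D^{-1/2}`` where D is the degree matrix of
    A + I.  An isolated node maps to a unit self-loop.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A < 0):
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _forward(X, S_hat, weights, slopes) -> Tensor:
    H = as_tensor(X)
    S = as_tensor(S_hat)
    for W, a in zip(weights, slopes):
        H = prelu(matmul(matmul(W, H), S), a)
    return H


def encode(X, S_hat, params: ModelParams) -> Tensor:
    """Spot embeddings H = PReLU(W_e X S), one column per spot."""
    return _forward(X, S_hat, params.enc_weights, params.enc_slopes)


def decode(H, S_hat, params: ModelParams) -> Tensor:
    """Reconstruction X' = PReLU(W_d H S), mirroring the encoder."""
    return _forward(H, S_hat, params.dec_weights, params.dec_slopes)


def readout(H_view) -> Tensor:
    """Global summary: sigmoid of the per-dimension mean over spots.

    Permutation-invariant in the spots, so the summary describes the
    whole view rather than any ordering of it.
    """
    H = as_tensor(H_view)
    return sigmoid(H.mean(axis=1))


def discriminate(h, c1, c2, W) -> float:
    """Probability that spot embedding h belongs with contexts c1, c2.

    Bilinear scoring averaged over the two contexts:
    sigmoid((h'W c1 + h'W c2) / 2).
    """
    h = np.asarray(h, dtype=np.float64).ravel()
    c1 = np.asarray(c1, dtype=np.float64).ravel()
    c2 = np.asarray(c2, dtype=np.float64).ravel()
    W = np.asarray(W.data if isinstance(W, Tensor) else W, dtype=np.float64)
    u = 0.5 * (h @ W @ c1 + h @ W @ c2)
    return float(1.0 / (1.0 + np.exp(-u)))


def _bilinear_scores(H: Tensor, ctx: Tensor, W: Tensor) -> Tensor:
    """Per-spot score u_i = h_i' W c_i (ctx broadcast if a column)."""
    return (H * matmul(W, ctx)).sum(axis=0)


def _contrastive(H, H_neg, ctx_pos, ctx_neg, W) -> Tensor:
    n = H.shape[1]
    u_pos = _bilinear_scores(as_tensor(H), ctx_pos, as_tensor(W))
    u_neg = _bilinear_scores(as_tensor(H_neg), ctx_neg, as_tensor(W))
    p = clip(sigmoid(u_pos), EPS, 1.0 - EPS)
    q = clip(sigmoid(u_neg), EPS, 1.0 - EPS)
    return -(log(p).sum() + log(1.0 - q).sum()) / (2.0 * n)


def loss_local_global(H, H_neg, s1, s2, W_disc_global) -> Tensor:
    """Local-global contrastive loss.

    Spot embeddings of the original graph are pulled toward the global
    summaries s1, s2 of the two positive views; shuffled-feature
    embeddings are pushed away.  With a constant-1/2 discriminator the
    value is log 2.
    """
    s1 = as_tensor(s1).reshape(-1, 1)
    s2 = as_tensor(s2).reshape(-1, 1)
    ctx = (s1 + s2) * 0.5
    return _contrastive(H, H_neg, ctx, ctx, W_disc_global)


def loss_subspace(H, H_neg, Z1, Z2, W_disc_sub) -> Tensor:
    """Local-subspace contrastive loss.

    Same form as the local-global loss, but each spot is scored against
    its own subspace-reconstructed context columns z1_i, z2_i instead of
    a single global summary.
    """
    ctx = (as_tensor(Z1) + as_tensor(Z2)) * 0.5
    return _contrastive(H, H_neg, ctx, ctx, W_disc_sub)


def loss_recon(X, X_prime) -> Tensor:
    """Reconstruction loss (1/n) ||X - X'||_F^2 over n spots."""
    X = as_tensor(X)
    Xp = as_tensor(X_prime)
    if X.shape != Xp.shape:
        raise ValueError("X and X' must have the same shape")
    n = X.shape[1]
    return (X - Xp).square().sum() / n


def total_loss(l_global, l_sub, l_recon, lambda1: float = 1.0,
               lambda2: float = 1.0) -> Tensor:
    """Weighted objective L_global + lambda1 L_subspace + lambda2 L_recon."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return as_tensor(l_global) + lambda1 * as_tensor(l_sub) \
        + lambda2 * as_tensor(l_recon)
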