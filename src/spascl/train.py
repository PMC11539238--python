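"""Alternating optimisation: Adam on the network, closed-form C refresh.

Training alternates two very different solvers.  Every iteration takes
one Adam step on the contrastive + reconstruction objective; every
``refresh_every`` iterations (and at iteration 0) the embedding is
frozen, the self-expression system is solved in closed form, and the
augmentations are resampled.  Gradients never flow through C — it is a
refreshed constant between solves, not a learned parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import augment as aug
from . import model as mdl
from . import subspace as sub
from .autodiff import Tensor
from .io_preprocess import AdjacencyPair, STDataset

__all__ = ["TrainConfig", "TrainResult", "Adam", "train", "ablate"]


@dataclass
class TrainConfig:
    """Hyperparameters of the full pipeline (defaults are the paper-scale
    conventions for a section of ~10^3-10^4 spots)."""

    lr: float = 0.001
    max_iters: int = 500
    refresh_every: int = 100
    lambda1: float = 1.0
    lambda2: float = 1.0
    beta: float = 1.0
    hidden_dim: int = 64
    n_layers: int = 1
    k_S: int = 10
    k_E: int = 10
    alpha: float = 0.5
    mask_rate: float = 0.2
    edge_rate: float = 0.2
    top_k: int = 10
    kernel: str = "linear"
    edge_aug: str = "HS_image"
    use_c_star: bool = False
    identity_c_init: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.max_iters > 0 and self.refresh_every > self.max_iters:
            raise ValueError("refresh_every must be <= max_iters")
        if self.refresh_every < 1:
            raise ValueError("refresh_every must be >= 1")


@dataclass
class TrainResult:
    H: np.ndarray
    C: np.ndarray
    C_star: np.ndarray
    M: np.ndarray
    loss_trace: list = field(default_factory=list)
    params: Optional[mdl.ModelParams] = None
    config: Optional[TrainConfig] = None


class Adam:
    """Adam with the standard moment defaults and no weight decay."""

    def __init__(self, params: list, lr: float = 0.001,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def ablate(config: TrainConfig, switch: str) -> TrainConfig:
    """Ablation switches: drop the subspace term or the morphology prior."""
    if switch == "no_subspace":
        return replace(config, lambda1=0.0)
    if switch == "random_edge":
        return replace(config, edge_aug="edge")
    raise ValueError(f"unknown ablation switch: {switch!r}")


def train(
    ds: STDataset,
    adj: AdjacencyPair,
    config: TrainConfig,
    morphology: Optional[aug.MorphologyFeatures] = None,
) -> TrainResult:
    """Run the full alternating optimisation on a preprocessed section.

    ``ds.counts`` is taken as the preprocessed X (d x n).  The weighted
    blended adjacency drives graph normalisation; its binarised form is
    what augmentation perturbs.  Morphology features are required for
    the ``HS_image`` edge augmentation and ignored otherwise.
    """
    X = np.asarray(ds.counts, dtype=np.float64)
    d, n = X.shape
    A = adj.A_blend
    S_hat = mdl.sym_normalize(A)

    A_I = None
    if config.edge_aug == "HS_image":
        if morphology is None:
            raise ValueError("HS_image augmentation requires morphology features")
        A_I = aug.morphology_knn(morphology, min(config.k_S, n - 1))

    params = mdl.init_params(d, config.hidden_dim, config.n_layers,
                             seed=config.seed)
    opt = Adam(params.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)

    use_subspace = config.lambda1 > 0
    C = np.eye(n)
    M = np.eye(n)
    C_star = np.eye(n)
    views = None
    S2_hat = S_hat
    trace: list[dict] = []

    for it in range(config.max_iters):
        if it % config.refresh_every == 0:
            # closed-form refresh on the frozen embedding + new augmentations
            if use_subspace and not (it == 0 and config.identity_c_init):
                H_frozen = mdl.encode(X, S_hat, params).data
                K = sub.gram(H_frozen, config.kernel)
                C = sub.solve_self_expression(K, S_hat, config.beta)
                M, C_star = sub.topk_filter(C, config.top_k)
            aug_seed = int(rng.integers(0, 2**31 - 1))
            views = aug.build_views(X, A, A_I, config.mask_rate,
                                    config.edge_rate, aug_seed,
                                    edge_aug=config.edge_aug)
            S2_hat = mdl.sym_normalize(views.A2_pos)

        H = mdl.encode(X, S_hat, params)
        H_neg = mdl.encode(views.X_neg, S_hat, params)
        H1 = mdl.encode(views.X1_pos, S_hat, params)
        H2 = mdl.encode(views.X2_pos, S2_hat, params)

        s1 = mdl.readout(H1)
        s2 = mdl.readout(H2)
        l_global = mdl.loss_local_global(H, H_neg, s1, s2, params.W_disc_global)

        if use_subspace:
            C_used = Tensor(C_star if config.use_c_star else C)
            Z1 = H1 @ C_used
            Z2 = H2 @ C_used
            l_sub = mdl.loss_subspace(H, H_neg, Z1, Z2, params.W_disc_sub)
        else:
            l_sub = Tensor(0.0)

        X_prime = mdl.decode(H, S_hat, params)
        l_recon = mdl.loss_recon(X, X_prime)
        l_total = mdl.total_loss(l_global, l_sub, l_recon,
                                 config.lambda1, config.lambda2)

        if not np.isfinite(l_total.data):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: "
                f"global={l_global.data}, subspace={l_sub.data}, "
                f"recon={l_recon.data}"
            )
        trace.append({
            "iter": it,
            "global": float(l_global.data),
            "subspace": float(l_sub.data),
            "recon": float(l_recon.data),
            "total": float(l_total.data),
        })

        opt.zero_grad()
        l_total.backward()
        opt.step()

    H_final = mdl.encode(X, S_hat, params).data
    if use_subspace and config.max_iters > 0:
        K = sub.gram(H_final, config.kernel)
        C = sub.solve_self_expression(K, S_hat, config.beta)
        M, C_star = sub.topk_filter(C, config.top_k)
    return TrainResult(H_final, C, C_star, M, trace, params, config)
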