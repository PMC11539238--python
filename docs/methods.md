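# Methods

## Model

`spascl` treats spatial domain identification as unsupervised node
representation learning on a spot graph, followed by clustering.

**Graph construction.**  Expression is held as a gene-by-spot matrix
`X ∈ R^{d×n}`.  Two binary kNN graphs are built with Euclidean
distances: `A_S` on spot coordinates (k_S neighbours) and `A_E` on the
normalised log expression over the selected HVGs (k_E neighbours).  kNN
selection is asymmetric, so both graphs are symmetrised by union — an
edge exists if either endpoint selected the other — which preserves
every selected neighbour.  Distance ties resolve toward the lower spot
index (stable argsort), making graphs reproducible on degenerate
geometry such as duplicated coordinates.  The training graph is the
blend `A = (1−α)A_S + αA_E`; spatial neighbours capture contiguous
domains while expression neighbours connect spatially discontinuous
domains.

**Encoder/decoder.**  `Ŝ = D̂^{-1/2}(A+I)D̂^{-1/2}` is the symmetrically
normalised adjacency with self-loops (an isolated spot maps to a unit
self-loop).  The encoder is `H = PReLU(W_e X Ŝ)` with a learnable
scalar negative slope per layer (initialised 0.25); the decoder mirrors
it, `X′ = PReLU(W_d H Ŝ)`.  Depth defaults to 1 and is capped at 3:
deeper stacks of this propagation over-smooth neighbouring spots into
indistinguishable embeddings.

**Views.**  Each augmentation round produces: a node-masked positive
view (a uniformly chosen fraction `mask_rate` of *gene dimensions*
zeroed across all spots — masking whole genes, the coarsest granularity,
keeps spot profiles comparable); an edge-perturbed positive view; and a
negative view that shuffles spot columns while keeping the graph (the
standard corruption for local-global InfoMax objectives).  Edge
perturbation is morphology-guided when per-spot morphology features
exist: a kNN graph `A_I` over those features and a symmetric random
location matrix `L` (each disagreeing pair flagged independently with
probability `edge_rate`) define

    τ_A(A) = A ⊙ (1 − L⊙(A − A⊙A_I)) + (1−A) ⊙ (L⊙(A_I − A⊙A_I)).

An exhaustively tested identity: entries where `A = A_I` never change,
`τ_A` is the identity at `L = 0` and maps `A` to `A_I` at `L = 1`.  For
imageless data a domain-agnostic fallback drops each edge with
probability `edge_rate` and adds an equal number of random non-edges.
Because edge flips are defined on binary graphs, the weighted blend is
binarised (entry > 0) for augmentation; the weighted blend still drives
`Ŝ`.  Augmentations are resampled at every subspace refresh (not every
iteration), balancing stochasticity against the stability of the
contexts entering the subspace loss.

**Morphology features.**  From a histology image, 50×50-pixel patches
centred on each spot (zero-padded at borders) are resized to a fixed
input size and embedded by a pluggable extractor.  Built-ins are
per-channel pixel means and a seeded random linear projection; any
callable patch→vector (e.g. a CNN penultimate layer) can be supplied.
The synthetic generator can instead emit features directly.

**Losses.**  With `s_k = sigmoid(rowmean(Ĥ_k))` the view summaries and
a bilinear discriminator `D(h, c₁, c₂) = σ((hᵀWc₁ + hᵀWc₂)/2)`:

* local–global: `−(1/2n)[Σ_i log D(h_i, s₁, s₂) + Σ_j log(1 − D(h̃_j, s₁, s₂))]`
* local–subspace: the same form with per-spot contexts `z₁ᵢ, z₂ᵢ`, the
  columns of `Z_k = Ĥ_k C`, and a separate bilinear weight matrix (the
  two losses contrast different context types)
* reconstruction: `(1/n)‖X − X′‖²_F`
* total: `L_global + λ₁ L_subspace + λ₂ L_recon` (defaults 1:1:1).

Discriminator probabilities are clamped to `[1e-7, 1 − 1e-7]` so the
log terms stay finite; with a constant-½ discriminator both contrastive
losses equal `log 2` exactly, a closed form the tests pin.

**Subspace module.**  With `K` the Gram matrix of the current embedding
(linear `HᵀH` by default; RBF with the median-heuristic bandwidth
optional) the self-expression coefficients solve

    min_C ½‖Φ(H)ŜC − Φ(H)‖²_F + (β/2)‖C‖²_F
    ⇒  C = (ŜᵀKŜ + βI)^{-1} ŜᵀK,

computed as one SPD linear solve (never an explicit inverse; a 1e-8
diagonal jitter retries once if `K` is PSD only to round-off).  The
problem is strictly convex, so the closed form is the global minimum —
verified against an iterative solver in the tests.  Per column, the
`top_k` coefficients by **magnitude** are kept (`M`, `C* = M⊙C`);
magnitude ranking is the default because a spot's strongest
self-expression weights can be negative and discarding them would throw
away in-domain neighbours (signed ranking is available as an option).
`C` (unfiltered) feeds the contrastive contexts by default, matching
the defining equation `Z = ĤC`; a switch substitutes `C*` where the
filtered matrix is preferred as a denoised context.

**Training schedule.**  Adam (lr 0.001, default moments, no weight
decay), 500 iterations, full-graph batches.  At iteration 0 and every
`refresh_every = 100` iterations the embedding is frozen, `C` is
recomputed in closed form, and the augmentations are resampled;
gradients never flow through `C`.  The schedule is the literal reading
of "alternate network training and subspace optimisation every 100
iterations"; both constants are configurable.  `C` is initialised from
the untrained embedding so the subspace loss is defined from the first
step (an identity-C first window is available behind a flag).

**Clustering.**  Full-covariance Gaussian mixture at fixed K (best of
10 seeded restarts by likelihood) provides model-based clustering in
pure Python — filling the role an R `mclust` call would play, without a
cross-language dependency.  Louvain community detection runs on a kNN
graph of L2-normalised embedding columns, with the resolution bisected
(40 steps in [0.01, 10]) toward a requested cluster count.  ARI and NMI
(arithmetic-mean normalisation) score against references.  No spatial
label smoothing is applied after clustering.

## Defaults

| parameter | default | meaning |
|---|---|---|
| k_S, k_E | 10 | spatial / expression kNN neighbours (50 suits very dense sections) |
| α | 0.5 | expression weight in the blended graph |
| n_top | 3000 | HVGs kept (panels ≤ 3000 genes pass through) |
| target_sum | 1e4 | per-spot library size before log1p |
| hidden_dim | 64 | embedding dimension |
| n_layers | 1 | GCN depth (max 3) |
| lr / max_iters / refresh_every | 0.001 / 500 / 100 | Adam schedule |
| λ₁, λ₂, β | 1, 1, 1 | loss weights and ridge strength |
| mask_rate, edge_rate | 0.2 | fraction of genes masked / edge pairs flagged |
| top_k | 10 | co-domain neighbours kept per spot (matched to k_S) |
| kernel | linear | Gram matrix for self-expression |

`mask_rate`/`edge_rate` have no canonical published value; 0.2 is a
moderate perturbation standard for contrastive graph augmentation, and
both are logged in the run configuration.  HVG ranking uses
Seurat-style normalised dispersion (scanpy `flavor="seurat"` on
log-normalised data), recorded in dataset metadata.  Spots with zero
total counts are dropped with a warning by default (policies `keep` and
`error` exist): on sparse platforms empty spots are artefacts, not
observations.

## Synthetic data

The grid generator plants K contiguous domains (equal-height horizontal
bands, or rectangular blocks) on an `R×C` lattice; expression is
Gaussian in log space around a base mean of 2, with each domain's
disjoint marker set shifted by `effect_size` (default 3 noise SDs),
exponentiated and rounded to counts.  Morphology features are a noisy
one-hot domain code.  Defaults (20×30 grid, K = 3, 50 genes, 5
markers/domain, 3σ effect) give domains that a nearest-centroid
classifier separates at ≥ 99% — strong but not degenerate signal, sized
so a full 500-iteration run takes seconds on one CPU.  The
union-of-subspaces generator draws each class from a random orthonormal
basis (optionally mutually orthogonal bases) with standard-normal
coefficients plus ambient noise.

Passing on these fixtures shows the machinery is correct and that the
method recovers structure under its own assumptions; it does not
demonstrate performance on real tissue, where zero inflation, segment
boundary noise, and histology artefacts are absent from the simulation.

## Numerical choices

* Pure-NumPy reverse-mode autodiff (float64) powers training; analytic
  gradients are validated against central finite differences to < 1e-4
  relative error.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; same seed ⇒ bit-identical loss traces.
* kNN ties → lower index; top-k ties → smaller row; neighbour-majority
  ties → keep own label.  Each tie rule is pinned by a test.
* The SPD solve costs O(n³) per refresh and C is dense O(n²) — fine to
  a few thousand spots; anchor/landmark approximations are out of
  scope.

## Known limitations

Single-section analysis only (no multi-slice integration or batch
correction); no spot deconvolution; the subspace solve limits n before
memory/time dominate; trajectory inference, UMAP visualisation and
marker-gene dotplots are delegated to scanpy on the exported embedding
rather than reimplemented.
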