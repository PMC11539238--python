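# spascl

Spatial domain identification for spatial transcriptomics via
**subspace-enhanced, morphology-aware graph contrastive learning**.

Spatial transcriptomics (ST) platforms (10x Visium, Stereo-seq, MERFISH,
STARmap, …) measure gene expression at spatially resolved spots.  The
first analysis step is usually to partition the spots into *spatial
domains* — regions with coherent expression and morphology.  `spascl`
learns a low-dimensional spot embedding for this task by combining three
ingredients:

1. **Graph contrastive learning.**  Spots form a graph whose adjacency
   blends a spatial kNN graph and an expression kNN graph,
   `A = (1 − α)·A_S + α·A_E`.  A single-layer GCN encoder
   `H = PReLU(W_e X D̂^{-1/2}ÂD̂^{-1/2})` is trained to discriminate spot
   embeddings paired with summaries of two augmented positive views
   against a feature-shuffled negative view (a local–global
   InfoMax-style loss), plus a GCN decoder with reconstruction loss
   `(1/n)‖X − X′‖²_F`.
2. **Morphology-aware augmentation.**  When a histology image (or any
   per-spot morphology feature) is available, edge perturbation is
   guided by a morphology kNN graph `A_I`:
   `τ_A(A) = A⊙(1 − L⊙(A − A⊙A_I)) + (1 − A)⊙(L⊙(A_I − A⊙A_I))`,
   so only edges contradicted (or supported) by morphology are flipped.
3. **Subspace self-expression.**  Assuming spots of one domain lie near
   a common low-dimensional subspace, the coefficient matrix
   `C = (ŜᵀKŜ + βI)^{-1}ŜᵀK` (closed-form kernel ridge self-expression,
   `K` a linear or RBF Gram matrix of the embedding, `Ŝ` the normalised
   adjacency) supplies per-spot *co-domain contexts* `Z = Ĥ C` for a
   second, local–subspace contrastive loss.  Training alternates Adam
   steps on `L_global + λ₁·L_subspace + λ₂·L_recon` with closed-form C
   refreshes every 100 iterations.

The embedding is finally clustered with a full-covariance Gaussian
mixture or Louvain community detection, scored by ARI/NMI when reference
labels exist.  A synthetic-data module generates planted-domain grids
and union-of-subspaces point sets so the entire pipeline is testable
offline.

## Worked example

```python
from spascl.synthetic import SyntheticSpec, generate_grid_st
from spascl import io_preprocess as iop
from spascl.train import TrainConfig, train
from spascl.downstream import cluster_embedding

# 20x30 grid, 3 banded domains, 50 genes, 3-sigma marker shifts
ds, labels, morphology = generate_grid_st(SyntheticSpec(seed=1))
ds = iop.select_hvg(ds, 3000)            # panel < 3000 genes: unchanged
ds = iop.normalize_log(ds)               # library-size + log1p
adj = iop.build_graph(ds, k_spatial=10, k_expr=10, alpha=0.5)

result = train(ds, adj, TrainConfig(seed=1), morphology=morphology)
print(result.loss_trace[0]["total"], result.loss_trace[-1]["total"])
# 841.7639504476379 63.022703149430164   <- total loss, iteration 0 vs 499

cl = cluster_embedding(result.H, "gmm", 3, seed=0, ref=labels)
print(cl.score_table)
# {'ARI': 1.0, 'NMI': 1.0}               <- planted domains fully recovered
```

The loss falls by more than an order of magnitude over the 500 default
iterations, and Gaussian-mixture clustering of the learned 64-dimensional
embedding recovers the three planted bands exactly (ARI = NMI = 1).

The same pipeline is scriptable from the shell:

```bash
spascl simulate --seed 1 --out sim/
spascl preprocess --matrix sim/matrix.mtx --coords sim/coords.csv \
    --labels sim/labels.csv --out pre/
spascl train --data pre/ --out run/
spascl cluster --embedding run/embedding.npz --method gmm --k 3 \
    --ref sim/labels.csv --out pred.csv
spascl evaluate --pred pred.csv --ref sim/labels.csv
```

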