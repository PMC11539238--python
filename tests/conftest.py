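import numpy as np
import pytest

from spascl import io_preprocess as iop
from spascl.synthetic import SyntheticSpec, generate_grid_st


def make_grid_case(seed: int, spec_kwargs: dict | None = None):
    """Preprocessed planted-domain grid: (dataset, labels, morphology, adj)."""
    spec = SyntheticSpec(seed=seed, **(spec_kwargs or {}))
    ds, labels, feats = generate_grid_st(spec)
    ds = iop.select_hvg(ds, 3000)
    ds = iop.normalize_log(ds)
    adj = iop.build_graph(ds, k_spatial=10, k_expr=10, alpha=0.5)
    return ds, labels, feats, adj


@pytest.fixture
def small_grid():
    """A fast 8x10, 2-domain grid for unit-level training tests."""
    return make_grid_case(0, {"grid": (8, 10), "n_domains": 2,
                              "n_genes": 30, "markers_per_domain": 4})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def knn_oracle(points: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive O(n^2) k-nearest-neighbour graph, union-symmetrised,
    distance ties broken toward the lower index."""
    n = points.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        d = [(float(np.linalg.norm(points[i] - points[j])), j)
             for j in range(n) if j != i]
        d.sort()
        for _, j in d[:k]:
            A[i, j] = 1.0
    return np.maximum(A, A.T)
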