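import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from nichescape import DistanceMatrix, RegionSet


@pytest.fixture
def make_euclidean_dm():
    """Factory for a random Euclidean distance matrix from planted points."""

    def _make(n, seed=0, dim=3, name=None, labels=None):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0.0, 1.0, size=(n, dim))
        regions = RegionSet(labels if labels is not None
                            else (f"r{i}" for i in range(n)))
        return DistanceMatrix(squareform(pdist(pts)), regions, name=name)

    return _make


def random_additive_matrix(n_leaves, seed):
    """Leaf distances of a random binary tree with random edge lengths.

    The generating tree is the oracle: neighbor joining must reproduce
    these distances exactly.
    """
    rng = np.random.default_rng(seed)
    edges = {(0, 1): rng.uniform(0.2, 1.0)}
    next_id = 2
    leaves = [0, 1]
    while len(leaves) < n_leaves:
        # attach a new leaf to a random existing edge
        (a, b) = list(edges)[rng.integers(len(edges))]
        w = edges.pop((a, b))
        mid, leaf = next_id, next_id + 1
        next_id += 2
        split = rng.uniform(0.2, 0.8)
        edges[(a, mid)] = w * split
        edges[(mid, b)] = w * (1 - split)
        edges[(mid, leaf)] = rng.uniform(0.2, 1.0)
        leaves.append(leaf)
    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    mat = np.zeros((n_leaves, n_leaves))
    for i, u in enumerate(leaves):
        dist = {u: 0.0}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, v in enumerate(leaves):
            mat[i, j] = dist[v]
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, RegionSet(f"L{k}" for k in range(n_leaves)))


@pytest.fixture
def additive_matrix_factory():
    return random_additive_matrix


@pytest.fixture
def small_dataset():
    """A reduced synthetic dataset for structural tests."""
    from nichescape import SimulationConfig, simulate_dataset
    return simulate_dataset(SimulationConfig(
        n_regions=15, n_surnames=60, n_species=25, seed=42))
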