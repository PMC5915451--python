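"""Ward clustering and neighbor-joining summaries of distance matrices.

Ward clustering uses the Ward.D2 form (scipy's ``linkage`` on the raw
distances), which minimizes the increase in within-cluster variance at
each merge.  Neighbor joining is the canonical Saitou–Nei agglomeration
with the Q-criterion, implemented here so that ties break on the
lowest-index pair and negative branch-length estimates are clamped to
zero with the deficit transferred to the sibling edge (the path lengths
through the joined node are preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrix import DistanceMatrix
from .regions import RegionSet

log = logging.getLogger(__name__)

_QUOTE_TRIGGERS = set(" \t(),:;[]'")


def _newick_label(label: str) -> str:
    if any(ch in _QUOTE_TRIGGERS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------- Ward

@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence over a region set.

    ``linkage_matrix`` is in scipy format: row k merges clusters
    ``Z[k, 0]`` and ``Z[k, 1]`` at height ``Z[k, 2]`` into cluster
    ``n + k`` of size ``Z[k, 3]``.
    """

    linkage_matrix: np.ndarray
    regions: RegionSet

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame({
            "merge": np.arange(len(z)),
            "cluster_a": z[:, 0].astype(int),
            "cluster_b": z[:, 1].astype(int),
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        })

    def to_merge_csv(self, path) -> None:
        self.to_merge_table().to_csv(path, index=False, float_format="%.10g")

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Leaf label -> cluster id for a flat cut into ``n_clusters``."""
        from scipy.cluster.hierarchy import fcluster
        flat = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.regions.labels, (int(c) for c in flat)))

    def leaf_partition(self, k_merges: int) -> frozenset[frozenset[str]]:
        """Partition of the leaves after the first ``k_merges`` merges."""
        n = len(self.regions)
        members: dict[int, set[str]] = {i: {self.regions[i]}
                                        for i in range(n)}
        for m in range(k_merges):
            a, b = int(self.linkage_matrix[m, 0]), int(self.linkage_matrix[m, 1])
            members[n + m] = members.pop(a) | members.pop(b)
        return frozenset(frozenset(s) for s in members.values())

    def to_newick(self) -> str:
        """Rooted Newick; edge lengths split merge heights evenly, so
        leaf depths equal half the cophenetic distance."""
        n = len(self.regions)
        height = {i: 0.0 for i in range(n)}
        node = {i: _newick_label(self.regions[i]) for i in range(n)}
        for m, (a, b, h, _sz) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            node[n + m] = f"({node.pop(a)}:{la:.10g},{node.pop(b)}:{lb:.10g})"
            height[n + m] = h
        (root,) = node.values()
        return root + ";"


def ward_cluster(d: DistanceMatrix) -> Dendrogram:
    """Ward.D2 agglomerative clustering of a distance matrix."""
    if d.n < 2:
        raise ValueError("Ward clustering requires at least 2 regions")
    z = linkage(squareform(d.values, checks=False), method="ward")
    return Dendrogram(linkage_matrix=z, regions=d.regions)


# ---------------------------------------------------------------- NJ

@dataclass
class UnrootedTree:
    """Unrooted tree: leaves carry region labels, internal nodes have
    degree three; edges carry non-negative lengths."""

    leaves: tuple[str, ...]
    edges: list[tuple[int, int, float]]       # (node, node, length)
    labels: dict[int, str] = field(default_factory=dict)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        return adj

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaves."""
        adj = self.adjacency()
        leaf_nodes = {lab: node for node, lab in self.labels.items()}
        order = list(self.leaves)
        n = len(order)
        out = np.zeros((n, n))
        for i, lab in enumerate(order):
            # Dijkstra is overkill: trees have unique paths; BFS with sums
            start = leaf_nodes[lab]
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, lab2 in enumerate(order):
                out[i, j] = dist[leaf_nodes[lab2]]
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(out, RegionSet(order), validate=False)

    def to_newick(self) -> str:
        """Newick rooted at an internal node (trifurcating root)."""
        adj = self.adjacency()
        internal = [u for u, nb in adj.items() if len(nb) > 1]
        root = internal[0] if internal else next(iter(adj))

        def render(u: int, parent: int | None) -> str:
            children = [(v, w) for v, w in adj[u] if v != parent]
            if not children and u in self.labels:
                return _newick_label(self.labels[u])
            parts = [f"{render(v, u)}:{w:.10g}" for v, w in sorted(children)]
            return "(" + ",".join(parts) + ")"

        return render(root, None) + ";"


def neighbor_joining(d: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbor joining of a distance matrix.

    Exact on additive (tree-metric) inputs.  Ties in the Q-criterion are
    broken by the lowest (i, j) index pair; negative branch-length
    estimates are clamped to zero with the deficit moved to the sibling
    branch, preserving the joined pair's path length.
    """
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 regions")
    labels = list(d.regions.labels)
    dist = d.values.copy()
    active = list(range(n))                      # indices into dist
    node_id = list(range(n))                     # tree node per active index
    next_node = n
    edges: list[tuple[int, int, float]] = []

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            log.debug("clamping negative branch %.3g", li)
            lj += li
            li = 0.0
        if lj < 0:
            log.debug("clamping negative branch %.3g", lj)
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin scans row-major, first hit wins
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)

        u = next_node
        next_node += 1
        edges.append((u, node_id[i], li))
        edges.append((u, node_id[j], lj))

        # distances from the new node to the remaining active nodes
        new_row = np.zeros(dist.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (dist[i, k] + dist[j, k] - dij) / 2.0
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        new_index = dist.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]
        # node_id stays aligned with matrix row indices; rows for i and j
        # remain allocated but inactive
        node_id.append(u)

    # final three-way join: closed-form star branch lengths
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    center = next_node
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            log.debug("clamping negative terminal branch %.3g", lk)
            lk = 0.0
        edges.append((center, node_id[k], lk))

    labels_map = {i: labels[i] for i in range(n)}
    return UnrootedTree(leaves=tuple(labels), edges=edges, labels=labels_map)


def write_newick(obj: UnrootedTree | Dendrogram, path=None) -> str:
    """Serialize a tree or dendrogram to Newick; optionally write a file."""
    text = obj.to_newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text
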