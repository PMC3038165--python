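"""Neighbor-joining trees and nonparametric bootstrap support.

The agglomeration is the canonical Saitou-Nei procedure (Q criterion and the
standard branch-length formulas), which recovers the generating topology and
branch lengths exactly on additive matrices. Exact Q ties are resolved by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf label) so results are reproducible across platforms.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sister edge, the usual practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tree", "nj_tree", "bootstrap_support", "bipartition"]

_TIE_TOL = 1e-10


def bipartition(side: Iterable[str], all_labels: Iterable[str]) -> frozenset[str]:
    """Canonical form of an unrooted split: the side not holding the smallest label."""
    side = frozenset(side)
    universe = frozenset(all_labels)
    anchor = min(universe)
    return side if anchor not in side else universe - side


@dataclass
class Tree:
    """Unrooted (or rooted) tree over integer node ids.

    Leaves are ids ``0..n_leaves-1`` in the order of ``leaf_labels``; edges
    are ``(parent-ish id, child-ish id, length)`` triples — orientation is
    arbitrary for unrooted trees and only adjacency is meaningful.
    """

    leaf_labels: list[str]
    edges: list[tuple[int, int, float]]
    n_nodes: int
    support: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for u, v, w in self.edges:
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj

    def rooted_at(self, label: str) -> tuple[int, dict[int, list[int]], dict[int, frozenset[str]]]:
        """Root at a leaf; returns (root id, children map, leafset per node)."""
        root = self.leaf_labels.index(label)
        adj = self.adjacency()
        children: dict[int, list[int]] = {}
        order: list[int] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            kids = [v for v, _ in adj[node] if v != parent]
            children[node] = kids
            order.append(node)
            stack.extend((k, node) for k in kids)
        leafsets: dict[int, frozenset[str]] = {}
        for node in reversed(order):
            if node < self.n_leaves and not children[node]:
                leafsets[node] = frozenset({self.leaf_labels[node]})
            elif node < self.n_leaves:
                leafsets[node] = frozenset({self.leaf_labels[node]}).union(
                    *(leafsets[k] for k in children[node])
                )
            else:
                leafsets[node] = frozenset().union(*(leafsets[k] for k in children[node]))
        return root, children, leafsets

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits in canonical form."""
        if self.n_leaves < 4:
            return set()
        root, children, leafsets = self.rooted_at(self.leaf_labels[0])
        out: set[frozenset[str]] = set()
        universe = frozenset(self.leaf_labels)
        for node, ls in leafsets.items():
            if node == root or node < self.n_leaves:
                continue
            if 1 < len(ls) < self.n_leaves - 1:
                out.add(bipartition(ls, universe))
        return out

    def path_distances(self) -> np.ndarray:
        """Leaf-to-leaf path-length matrix in ``leaf_labels`` order."""
        adj = self.adjacency()
        n = self.n_leaves
        out = np.zeros((n, n))
        for leaf in range(n):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other in range(n):
                out[leaf, other] = dist[other]
        return out

    def newick(self, with_support: bool = False) -> str:
        adj = self.adjacency()
        start = max(range(self.n_nodes), key=lambda i: len(adj[i]))
        universe = frozenset(self.leaf_labels)

        def leafset(node: int, parent: int) -> frozenset[str]:
            if node < self.n_leaves:
                return frozenset({self.leaf_labels[node]})
            out: set[str] = set()
            for v, _ in adj[node]:
                if v != parent:
                    out |= leafset(v, node)
            return frozenset(out)

        def fmt(node: int, parent: int, length: float | None) -> str:
            if node < self.n_leaves:
                body = self.leaf_labels[node]
            else:
                parts = [fmt(v, node, w) for v, w in adj[node] if v != parent]
                body = "(" + ",".join(parts) + ")"
                if with_support and parent >= 0:
                    key = bipartition(leafset(node, parent), universe)
                    if key in self.support:
                        body += f"{self.support[key]:g}"
            if length is not None:
                body += f":{length:.6g}"
            return body

        return fmt(start, -1, None) + ";"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return la, max(lb, 0.0)


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree; exact on additive matrices. Two taxa yield the
    degenerate single-edge tree (split evenly), three the star resolved by
    the three-point formulas.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if n < 2:
        raise ValueError("need at least two taxa")
    labels = [str(x) for x in labels]
    if len(set(labels)) != n:
        raise ValueError("leaf labels must be unique")
    if n == 2:
        half = d[0, 1] / 2.0
        return Tree(labels, [(2, 0, half), (2, 1, half)], 3)

    work = d.copy()
    node_ids = list(range(n))          # current cluster -> tree node id
    tie_labels = list(labels)          # min leaf label per cluster
    edges: list[tuple[int, int, float]] = []
    next_id = n

    while len(node_ids) > 3:
        m = work.shape[0]
        r = work.sum(axis=1)
        q = (m - 2) * work - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + _TIE_TOL)
        best = min(
            (tuple(sorted((tie_labels[i], tie_labels[j]))), i, j)
            for i, j in ties
            if i < j
        )
        i, j = best[1], best[2]
        la = 0.5 * work[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lb = work[i, j] - la
        la, lb = _clamp_pair(la, lb)
        new = next_id
        next_id += 1
        edges.append((new, node_ids[i], la))
        edges.append((new, node_ids[j], lb))
        dk = 0.5 * (work[i, :] + work[j, :] - work[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        work = np.vstack([work[keep][:, keep], dk[keep][None, :]])
        work = np.hstack([work, np.append(dk[keep], 0.0)[:, None]])
        node_ids = [node_ids[k] for k in keep] + [new]
        tie_labels = [tie_labels[k] for k in keep] + [min(tie_labels[i], tie_labels[j])]

    center = next_id
    next_id += 1
    if len(node_ids) == 3:
        d01, d02, d12 = work[0, 1], work[0, 2], work[1, 2]
        l0 = (d01 + d02 - d12) / 2.0
        l1 = (d01 + d12 - d02) / 2.0
        l2 = (d02 + d12 - d01) / 2.0
        for node, length in zip(node_ids, (l0, l1, l2)):
            edges.append((center, node, max(length, 0.0)))
    else:  # two clusters left (possible when n == 2 handled above; defensive)
        edges.append((node_ids[0], node_ids[1], work[0, 1]))
        next_id -= 1
    return Tree(labels, edges, next_id)


def bootstrap_support(
    columns: np.ndarray,
    labels: Sequence[str],
    tree_builder: Callable[[np.ndarray], Tree],
    n_replicates: int,
    seed: int,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap.

    ``columns`` is an encoded alignment (n_taxa, n_columns); ``tree_builder``
    maps such an array to a Tree over ``labels``. Returns the full-data tree
    annotated with the percentage of replicate trees containing each of its
    internal splits.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_cols = columns.shape[1]
    if n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")
    full = tree_builder(columns)
    targets = full.bipartitions()
    counts = {b: 0 for b in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = tree_builder(columns[:, idx])
        for b in rep.bipartitions():
            if b in counts:
                counts[b] += 1
    full.support = {b: 100.0 * c / n_replicates for b, c in counts.items()}
    return full, full.support
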