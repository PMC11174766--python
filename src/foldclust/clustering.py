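"""UPGMA clustering, ultrametric dendrograms, and Newick serialization.

UPGMA (unweighted pair group method with arithmetic mean) repeatedly
merges the two clusters with the smallest average inter-cluster distance;
the average is over all leaf pairs of the original matrix, maintained
incrementally by size-weighted updates.  The merge "height" recorded here
is that minimal average distance itself, so the cophenetic distance
between two leaves equals the height of their lowest common merge.  In
the Newick output the tree is drawn ultrametrically: node depths are half
the merge heights, so the leaf-to-leaf path length through the tree
reproduces the cophenetic distance.

Ties in the minimal distance are broken deterministically by the
lexicographically smallest (min leaf label of one cluster, min leaf label
of the other), which makes the tree invariant to the input row order.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric merge tree.

    Nodes are numbered scipy-style: leaf ``i`` is node ``i`` for
    ``i < n``; the ``m``-th merge (0-based) creates node ``n + m``.
    ``merges[m] = (left, right, height)`` with heights non-decreasing;
    heights are on the distance scale (cophenetic heights).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(h < 0 for h in heights):
            raise ValueError("merge heights must be non-negative")
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_members(self) -> list[frozenset[int]]:
        """Leaf-index set of every node (leaves first, then merges in order)."""
        n = len(self.leaves)
        members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for left, right, _ in self.merges:
            members.append(members[left] | members[right])
        return members


def upgma(D: np.ndarray, ids: list[str]) -> Dendrogram:
    """Classic UPGMA agglomeration of a symmetric zero-diagonal distance matrix."""
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} does not match {n} ids")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if D.min() < 0:
        raise ValueError("distances must be non-negative")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")

    # active cluster state: node id -> (size, min leaf label)
    size = {i: 1 for i in range(n)}
    min_label = {i: ids[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        dmin = min(dist[k] for k in dist)
        best_key = None
        best_pair = None
        for (a, b), d in dist.items():
            if d != dmin:
                continue
            la, lb = min_label[a], min_label[b]
            key = (la, lb) if la <= lb else (lb, la)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b) if la <= lb else (b, a)
        assert best_pair is not None
        left, right = best_pair  # left has the smaller min leaf label
        new = next_node
        next_node += 1
        merges.append((left, right, dmin))
        na, nb = size[left], size[right]
        for other in active:
            if other in (left, right):
                continue
            ka = (min(left, other), max(left, other))
            kb = (min(right, other), max(right, other))
            dnew = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            del dist[ka], dist[kb]
            dist[(min(new, other), max(new, other))] = dnew
        del dist[(min(left, right), max(left, right))]
        active.discard(left)
        active.discard(right)
        active.add(new)
        size[new] = na + nb
        min_label[new] = min(min_label[left], min_label[right])
    return Dendrogram(tuple(ids), tuple(merges))


def _quote(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Dendrogram) -> str:
    """Rooted Newick with ultrametric branch lengths (6-decimal fixed format).

    A child branch spans (parent merge height − child merge height) / 2 on
    the tree-depth scale, so leaf-to-leaf path lengths equal cophenetic
    distances; leaves sit at height 0.
    """
    n = t.n_leaves
    height = [0.0] * n + [h for _, _, h in t.merges]

    def render(node: int, parent_h: float) -> str:
        bl = (parent_h - height[node]) / 2.0
        if node < n:
            return f"{_quote(t.leaves[node])}:{bl:.6f}"
        left, right, h = t.merges[node - n]
        return f"({render(left, h)},{render(right, h)}):{bl:.6f}"

    root = n + len(t.merges) - 1
    left, right, h = t.merges[-1]
    return f"({render(left, h)},{render(right, h)});"


def write_newick(t: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(t) + "\n")


def from_newick(text: str) -> Dendrogram:
    """Parse a rooted binary ultrametric Newick string back to a Dendrogram.

    Intended for round-tripping trees written by :func:`to_newick`; node
    heights are reconstructed from root-to-node depths assuming leaves
    are equidistant from the root (ultrametricity).
    """
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")
    root = tree.seed_node
    depth: dict = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaf_nodes = [nd for nd in tree.leaf_node_iter()]
    max_depth = max(depth[nd] for nd in leaf_nodes)
    leaves = tuple(nd.taxon.label for nd in leaf_nodes)
    index = {nd: i for i, nd in enumerate(leaf_nodes)}
    n = len(leaves)
    internal = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    internal.sort(key=lambda nd: max_depth - depth[nd])  # ascending height
    merges: list[tuple[int, int, float]] = []
    node_id: dict = dict(index)
    for m, nd in enumerate(internal):
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError("from_newick supports binary trees only")
        left, right = (node_id[c] for c in children)
        h = 2.0 * (max_depth - depth[nd])  # depth scale -> cophenetic scale
        merges.append((min(left, right), max(left, right), max(h, 0.0)))
        node_id[nd] = n + m
    return Dendrogram(leaves, tuple(merges))


def cophenetic_matrix(t: Dendrogram) -> np.ndarray:
    """Pairwise cophenetic distances: height of the lowest common merge."""
    n = t.n_leaves
    C = np.zeros((n, n))
    members = t.node_members()
    done = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(done, True)
    for k, (left, right, h) in enumerate(t.merges):
        li = sorted(members[left])
        ri = sorted(members[right])
        for i in li:
            for j in ri:
                if not done[i, j]:
                    C[i, j] = C[j, i] = h
                    done[i, j] = done[j, i] = True
    return C


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    """Flat clusters from removing the ``k - 1`` highest merges.

    Clusters are indexed 0..k-1 deterministically by their smallest member
    label.  ``k = 1`` returns one cluster; ``k = n`` all singletons.
    """
    n = t.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # union through the first n - k merges; merge node m is node n + m
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (left, right, _) in enumerate(t.merges[: n - k]):
        node = n + m
        parent[find(left)] = node
        parent[find(right)] = node
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(t.leaves[i])
    ordered = sorted(groups.values(), key=lambda g: min(g))
    return {leaf: ci for ci, group in enumerate(ordered) for leaf in group}
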