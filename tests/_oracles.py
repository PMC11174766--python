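"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from its definition by a different
route than the library (exhaustive search, per-step recomputation from
the original matrix, plain-Python DP), so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_min_rmsd(P: np.ndarray, Q: np.ndarray, step_deg: float = 2.0) -> float:
    """Minimal RMSD over proper rotations by brute-force Euler-angle grid.

    Centers both sets, then scans z-y-z Euler angles on a ``step_deg``
    grid.  Upper-bounds the true optimum to within the grid resolution.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    a = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    b = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    best = np.inf
    ca, sa = np.cos(a), np.sin(a)
    for bb in b:
        cb, sb = np.cos(bb), np.sin(bb)
        for cc in np.deg2rad(np.arange(0.0, 360.0, step_deg)):
            c2, s2 = np.cos(cc), np.sin(cc)
            # R = Rz(a) @ Ry(b) @ Rz(c), vectorized over a
            R = np.empty((len(a), 3, 3))
            R[:, 0, 0] = ca * cb * c2 - sa * s2
            R[:, 0, 1] = -ca * cb * s2 - sa * c2
            R[:, 0, 2] = ca * sb
            R[:, 1, 0] = sa * cb * c2 + ca * s2
            R[:, 1, 1] = -sa * cb * s2 + ca * c2
            R[:, 1, 2] = sa * sb
            R[:, 2, 0] = -sb * c2
            R[:, 2, 1] = sb * s2
            R[:, 2, 2] = cb
            PR = np.einsum("kij,nj->kni", R, P)
            d2 = np.mean(np.sum((PR - Q[None]) ** 2, axis=2), axis=1)
            m = d2.min()
            if m < best:
                best = m
    return float(np.sqrt(best))


def brute_force_upgma(D: np.ndarray, ids: list[str]):
    """UPGMA recomputing every average linkage from the ORIGINAL matrix.

    Returns (merge label-sets, heights): at each step the average
    inter-cluster distance is recomputed as the mean over all original
    leaf pairs, instead of the incremental size-weighted update.  Ties
    broken by the lexicographically smallest (min label, min label) pair.
    """
    n = len(ids)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    heights = []
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            cx, cy = clusters[x], clusters[y]
            d = np.mean([D[i, j] for i in cx for j in cy])
            lx = min(ids[i] for i in cx)
            ly = min(ids[i] for i in cy)
            key = (d, min(lx, ly), max(lx, ly))
            if best is None or key < best[0]:
                best = (key, x, y)
        (d, _, _), x, y = best
        merges.append((frozenset(ids[i] for i in clusters[x]),
                       frozenset(ids[i] for i in clusters[y])))
        heights.append(d)
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return merges, heights


def nw_identity_oracle(a: str, b: str) -> float:
    """Plain-Python global alignment identity (match +1/mismatch 0/gap −1)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        H[i][0] = -i
    for j in range(m + 1):
        H[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else 0
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - 1, H[i][j - 1] - 1)
    matches = columns = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0):
            matches += 1 if a[i - 1] == b[j - 1] else 0
            columns += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i][j] == H[i - 1][j] - 1:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return matches / columns


def tree_bipartitions(newick_tree) -> set[frozenset[str]]:
    """Non-trivial splits of a dendropy tree, normalized away from a reference leaf."""
    taxa = {lf.taxon.label for lf in newick_tree.leaf_node_iter()}
    ref = min(taxa)
    splits = set()
    for node in newick_tree.preorder_internal_node_iter(exclude_seed_node=True):
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(clade) < 2 or len(clade) > len(taxa) - 2:
            continue
        if ref in clade:
            clade = frozenset(taxa - clade)
        splits.add(clade)
    return splits


def random_ultrametric(n: int, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """A random ultrametric distance matrix built from a random merge tree."""
    ids = [f"t{i:02d}" for i in range(n)]
    clusters = [[i] for i in range(n)]
    D = np.zeros((n, n))
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.05, 1.0))
        x, y = sorted(rng.choice(len(clusters), size=2, replace=False))
        for i in clusters[x]:
            for j in clusters[y]:
                D[i, j] = D[j, i] = h
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return D, ids
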