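"""Structure-vs-sequence grouping concordance.

Structure-based clustering can disagree with sequence-based grouping:
proteins with divergent sequences may still share a fold, and vice versa.
This module builds a transparent sequence baseline (pairwise global
alignment identity → UPGMA) and quantifies agreement between the two
trees with standard statistics:

* Robinson–Foulds distance (bipartitions present in exactly one tree),
* adjusted Rand index of each tree's flat clusters against reference
  subfamily labels,
* Pearson correlation of the two cophenetic distance matrices,
* the set of leaves whose cluster co-membership differs between trees
  (the concrete "which proteins moved" answer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.stats import pearsonr

from .clustering import Dendrogram, cophenetic_matrix, cut_tree, upgma

_ALPHABET = "ACDEFGHIKLMNPQRSTVWXY"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence keyed by the same id as its structure."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - set(_ALPHABET)
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.seq), 60):
                fh.write(rec.seq[k : k + 60] + "\n")


@njit(cache=True)
def _nw_identity(a, b):  # pragma: no cover - exercised via sequence_distance_matrix
    """Global NW (match +1, mismatch 0, linear gap −1); returns (matches, columns).

    Traceback ties prefer diagonal, then up (gap in b), then left.
    """
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    for i in range(n + 1):
        H[i, 0] = -i
    for j in range(m + 1):
        H[0, j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else 0
            best = H[i - 1, j - 1] + s
            if H[i - 1, j] - 1 > best:
                best = H[i - 1, j] - 1
            if H[i, j - 1] - 1 > best:
                best = H[i, j - 1] - 1
            H[i, j] = best
    matches = 0
    columns = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = 1 if a[i - 1] == b[j - 1] else 0
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += s
                columns += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] - 1:
            columns += 1
            i -= 1
            continue
        columns += 1
        j -= 1
    return matches, columns


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the global alignment of two sequences."""
    matches, columns = _nw_identity(_encode(a), _encode(b))
    return matches / columns


def sequence_distance_matrix(records: list[SequenceRecord]) -> tuple[np.ndarray, list[str]]:
    """All-pairs ``1 − identity`` distances from global alignment."""
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    enc = [_encode(r.seq) for r in records]
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matches, columns = _nw_identity(enc[i], enc[j])
            D[i, j] = D[j, i] = 1.0 - matches / columns
    return D, ids


def sequence_tree(records: list[SequenceRecord]) -> Dendrogram:
    """UPGMA tree over pairwise alignment-identity distances."""
    D, ids = sequence_distance_matrix(records)
    return upgma(D, ids)


def _bipartitions(t: Dendrogram) -> set[frozenset[str]]:
    """Non-trivial splits, each normalized to the side not containing the
    lexicographically smallest leaf."""
    n = t.n_leaves
    ref = min(t.leaves)
    leafsets = t.node_members()
    splits: set[frozenset[str]] = set()
    all_idx = frozenset(range(n))
    for node in range(n, n + len(t.merges)):
        clade = leafsets[node]
        if len(clade) < 2 or len(clade) > n - 2:
            continue
        names = frozenset(t.leaves[i] for i in clade)
        if ref in names:
            names = frozenset(t.leaves[i] for i in (all_idx - clade))
        splits.add(names)
    return splits


def robinson_foulds(t1: Dendrogram, t2: Dendrogram) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    if set(t1.leaves) != set(t2.leaves):
        raise ValueError("trees must share an identical leaf set")
    s1, s2 = _bipartitions(t1), _bipartitions(t2)
    return len(s1 ^ s2)


def rf_max(n_leaves: int) -> int:
    """Maximal RF distance between two binary trees on ``n`` leaves: 2(n−3)."""
    return max(0, 2 * (n_leaves - 3))


def adjusted_rand_index(p1: dict[str, int | str], p2: dict[str, int | str]) -> float:
    """Chance-corrected partition agreement from the contingency table.

    1 for identical partitions (label names irrelevant), ≈0 for independent
    ones.  When the correction denominator vanishes (e.g. both partitions
    all-singletons), returns 1.0 if co-membership is identical, else 0.0.
    """
    if set(p1) != set(p2):
        raise ValueError("partitions must cover the same ids")
    ids = sorted(p1)
    n = len(ids)
    labels1 = sorted({p1[i] for i in ids}, key=str)
    labels2 = sorted({p2[i] for i in ids}, key=str)
    l1 = {lab: k for k, lab in enumerate(labels1)}
    l2 = {lab: k for k, lab in enumerate(labels2)}
    cont = np.zeros((len(labels1), len(labels2)), dtype=np.int64)
    for i in ids:
        cont[l1[p1[i]], l2[p2[i]]] += 1

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = int(np.sum(comb2(cont)))
    a = int(np.sum(comb2(cont.sum(axis=1))))
    b = int(np.sum(comb2(cont.sum(axis=0))))
    total = comb2(n)
    expected = a * b / total if total else 0.0
    maximum = (a + b) / 2.0
    if maximum == expected:
        same = all(
            (p1[x] == p1[y]) == (p2[x] == p2[y]) for x in ids for y in ids
        )
        return 1.0 if same else 0.0
    return float((sum_ij - expected) / (maximum - expected))


@dataclass(frozen=True)
class ComparisonReport:
    """Concordance statistics between a structure tree and a sequence tree."""

    rf: int
    rf_max: int
    ari_structure: float | None
    ari_sequence: float | None
    coph_corr: float
    discordant_ids: tuple[str, ...]
    k: int

    def to_dict(self) -> dict:
        return {
            "rf": self.rf,
            "rf_max": self.rf_max,
            "ari_structure": self.ari_structure,
            "ari_sequence": self.ari_sequence,
            "coph_corr": self.coph_corr,
            "discordant_ids": list(self.discordant_ids),
            "k": self.k,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [
            f"Robinson-Foulds distance: {self.rf} / {self.rf_max} (max)",
            f"Cophenetic correlation (structure vs sequence): {self.coph_corr:.4f}",
            f"Flat clusters at k={self.k}:",
        ]
        if self.ari_structure is not None:
            lines.append(f"  ARI structure clusters vs reference labels: {self.ari_structure:.4f}")
            lines.append(f"  ARI sequence  clusters vs reference labels: {self.ari_sequence:.4f}")
        if self.discordant_ids:
            lines.append(
                f"  {len(self.discordant_ids)} ids grouped differently by structure and "
                f"sequence: {', '.join(self.discordant_ids)}"
            )
        else:
            lines.append("  structure and sequence clusters are fully concordant")
        return "\n".join(lines)


def compare_trees(
    structure_tree: Dendrogram,
    seq_tree: Dendrogram,
    labels: dict[str, str] | None = None,
    k: int | None = None,
) -> ComparisonReport:
    """Quantify structure-vs-sequence grouping concordance.

    Flat clusters are cut from both trees at ``k`` (default: the number of
    distinct reference labels).  ``discordant_ids`` are the leaves whose
    set of cluster co-members differs between the two trees — the ids a
    sequence-based grouping would place elsewhere than structure does.
    """
    if set(structure_tree.leaves) != set(seq_tree.leaves):
        raise ValueError("trees must share an identical leaf set")
    leaves = sorted(structure_tree.leaves)
    if labels is not None:
        missing = [l for l in leaves if l not in labels]
        if missing:
            raise ValueError(f"labels missing for: {missing[:5]}")
    if k is None:
        if labels is None:
            raise ValueError("k is required when no reference labels are given")
        k = len(set(labels[l] for l in leaves))
    ps = cut_tree(structure_tree, k)
    pq = cut_tree(seq_tree, k)
    ari_structure = ari_sequence = None
    if labels is not None:
        ref = {l: labels[l] for l in leaves}
        ari_structure = adjusted_rand_index(ps, ref)
        ari_sequence = adjusted_rand_index(pq, ref)

    order1 = {l: i for i, l in enumerate(structure_tree.leaves)}
    order2 = {l: i for i, l in enumerate(seq_tree.leaves)}
    C1 = cophenetic_matrix(structure_tree)
    C2 = cophenetic_matrix(seq_tree)
    iu = np.triu_indices(len(leaves), k=1)
    perm1 = [order1[l] for l in leaves]
    perm2 = [order2[l] for l in leaves]
    v1 = C1[np.ix_(perm1, perm1)][iu]
    v2 = C2[np.ix_(perm2, perm2)][iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        coph_corr = 1.0 if np.allclose(v1, v2) else 0.0
    else:
        coph_corr = float(pearsonr(v1, v2)[0])

    def comembers(part: dict[str, int], leaf: str) -> frozenset[str]:
        return frozenset(x for x in leaves if part[x] == part[leaf])

    discordant = tuple(
        sorted(l for l in leaves if comembers(ps, l) != comembers(pq, l))
    )
    return ComparisonReport(
        rf=robinson_foulds(structure_tree, seq_tree),
        rf_max=rf_max(len(leaves)),
        ari_structure=ari_structure,
        ari_sequence=ari_sequence,
        coph_corr=coph_corr,
        discordant_ids=discordant,
        k=k,
    )
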