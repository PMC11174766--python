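"""Fusion of TM-score and RMSD into a combined similarity, and matrix assembly.

TM-score and RMSD carry complementary information: TM-score is a bounded,
length-normalized fold-level similarity, while RMSD is an unbounded
deviation in Å over the aligned pairs.  The combined score is a convex
combination of TM-score and a normalized RMSD similarity

    combined = w_tm * tm + (1 - w_tm) * (1 - min(rmsd / r_max, 1))

so that it stays in [0, 1], equals 1 only for a perfect match, and
degrades with either signal.  The RMSD term saturates at ``r_max`` Å:
beyond that, structures are simply "different" and only TM-score
discriminates.  Defaults weight TM-score at 0.7 because it is the more
length-robust of the two signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScoringConfig:
    """Weights of the combined structural similarity.

    w_tm : weight of the TM-score term in [0, 1] (default 0.7).
    r_max : RMSD saturation in Å (default 10); pairs at or beyond this
        RMSD get zero credit from the RMSD term.
    """

    w_tm: float = 0.7
    r_max: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_tm <= 1.0):
            raise ValueError("w_tm must be in [0, 1]")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


@dataclass(frozen=True)
class PairwiseScore:
    """Scores for one unordered structure pair."""

    idA: str
    idB: str
    tm_sym: float
    rmsd: float
    combined: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.combined <= 1.0):
            raise ValueError("combined similarity must be in [0, 1]")


def combined_similarity(tm_sym: float, rmsd: float, cfg: ScoringConfig = ScoringConfig()) -> float:
    """Weighted fusion of TM-score and saturating normalized RMSD into [0, 1]."""
    if not (0.0 <= tm_sym <= 1.0):
        raise ValueError("tm_sym must be in [0, 1]")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    rmsd_sim = 1.0 - min(rmsd / cfg.r_max, 1.0)
    return cfg.w_tm * tm_sym + (1.0 - cfg.w_tm) * rmsd_sim


class SimilarityMatrix:
    """Symmetric, unit-diagonal similarity over an ordered id list."""

    def __init__(self, ids: list[str], S: np.ndarray):
        S = np.asarray(S, dtype=float)
        n = len(ids)
        if S.shape != (n, n):
            raise ValueError(f"matrix shape {S.shape} does not match {n} ids")
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.diag(S) == 1.0):
            raise ValueError("similarity matrix diagonal must be exactly 1")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self.ids = list(ids)
        self.S = S

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="id")


def similarity_matrix(pairs: list[PairwiseScore], ids: list[str]) -> SimilarityMatrix:
    """Assemble the symmetric unit-diagonal matrix from per-pair combined scores.

    Requires exactly one score per unordered pair of ``ids``; a missing
    pair or two conflicting scores for the same pair is an error.
    """
    index = {id_: k for k, id_ in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("ids must be unique")
    n = len(ids)
    S = np.full((n, n), np.nan)
    np.fill_diagonal(S, 1.0)
    for p in pairs:
        if p.idA not in index or p.idB not in index:
            raise ValueError(f"pair ({p.idA}, {p.idB}) references unknown id")
        i, j = index[p.idA], index[p.idB]
        if i == j:
            raise ValueError(f"self-pair for id {p.idA}")
        if not np.isnan(S[i, j]) and S[i, j] != p.combined:
            raise ValueError(f"conflicting duplicate scores for pair ({p.idA}, {p.idB})")
        S[i, j] = S[j, i] = p.combined
    missing = [
        (ids[i], ids[j]) for i in range(n) for j in range(i + 1, n) if np.isnan(S[i, j])
    ]
    if missing:
        raise ValueError(f"missing pair scores: {missing[:10]}" + (" ..." if len(missing) > 10 else ""))
    return SimilarityMatrix(ids, S)


def to_distance(sim: SimilarityMatrix) -> np.ndarray:
    """Elementwise ``D = 1 - S``: symmetric, zero diagonal, entries in [0, 1]."""
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return D


def write_distance_tsv(D: np.ndarray, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(D, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.6f", index_label="id"
    )


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square labelled matrix written by the TSV writers above."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)
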