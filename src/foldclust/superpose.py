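"""Rigid-body superposition and sequence-independent structural alignment.

The pairwise comparison engine: Kabsch least-squares superposition, RMSD,
TM-score with the standard length-dependent d0 normalization

    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8   (clamped below at 0.5 Å),

and an iterative TM-align-style alignment that needs no sequence
correspondence.  The alignment seeds candidate residue correspondences by
gapless threading of the shorter chain onto the longer at every offset,
then alternates (a) superposing on the current correspondence and
(b) re-deriving the correspondence by global affine dynamic programming on
the TM-score terms 1/(1 + (d_ij/d0)^2), until the correspondence is stable.
The candidate with the best symmetric TM-score wins.

TM-score is reported under both normalizations (by L(A) and by L(B)); the
symmetric TM (their mean) is what downstream similarity fusion consumes,
since clustering needs a symmetric matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .structures import ProteinStructure

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> R @ x + t``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1); reflections excluded")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class Correspondence:
    """Colinear residue pairing between two structures.

    ``pairs[k] = (i, j)`` matches residue position ``i`` of A (0-based) to
    position ``j`` of B; both index streams are strictly increasing and no
    index repeats on either side.
    """

    pairs: np.ndarray  # (m, 2) int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=int)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise ValueError("pairs must be a non-empty (m, 2) array")
        if np.any(np.diff(p[:, 0]) <= 0) or np.any(np.diff(p[:, 1]) <= 0):
            raise ValueError("correspondence indices must be strictly increasing on both sides")
        object.__setattr__(self, "pairs", p)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def full(cls, n: int) -> "Correspondence":
        idx = np.arange(n)
        return cls(np.stack([idx, idx], axis=1))


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise sequence-independent structural alignment."""

    correspondence: Correspondence
    transform: RigidTransform  # maps A onto B
    tm_ab: float  # TM normalized by L(A)
    tm_ba: float  # TM normalized by L(B)
    tm_sym: float  # mean of the two normalizations
    rmsd: float  # Å over the aligned pairs, after least-squares superposition
    n_aligned: int


def _kabsch_raw(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Unvalidated Kabsch core: returns (R, t, rmsd). Hot path for the aligner."""
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    X = P - cP
    Y = Q - cQ
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:
        Vt = Vt.copy()
        Vt[2] = -Vt[2]
    R = Vt.T @ U.T
    t = cQ - R @ cP
    diff = X @ R.T - Y
    rmsd = float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of matched point sets (P onto Q).

    Solves for the proper rotation and translation minimizing the RMSD of
    ``R @ P + t`` against ``Q`` via SVD of the cross-covariance; a
    reflection in the raw solution is excluded by flipping the sign of the
    smallest singular direction.  Requires ``n >= 3`` matched points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matched (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    X = P - P.mean(axis=0)
    # collinearity check via the 3x3 scatter spectrum (cheap)
    ev = np.linalg.eigvalsh(X.T @ X)
    if ev[1] <= 1e-12 * max(ev[2], 1.0):
        logger.warning("kabsch_superpose: degenerate (collinear) point set; solution not unique")
    R, t, rmsd = _kabsch_raw(P, Q)
    return RigidTransform(R, t), rmsd


def pair_rmsd(P: np.ndarray, Q: np.ndarray, transform: RigidTransform | None = None) -> float:
    """Root-mean-square deviation between matched points after ``transform``.

    Pure evaluator: any ``n >= 1`` is allowed (no superposition is done
    here; pass ``None`` for the identity).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have identical shapes")
    if transform is not None:
        P = transform.apply(P)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def tm_d0(L: int) -> float:
    """TM-score normalization distance d0(L), clamped below at 0.5 Å."""
    if L > 15:
        d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.0
    return max(d0, 0.5)


def tm_score(
    A: ProteinStructure | np.ndarray,
    B: ProteinStructure | np.ndarray,
    corr: Correspondence,
    transform: RigidTransform,
    L_norm: int,
) -> float:
    """TM-score of an aligned pair under a given normalization length.

    ``(1/L_norm) * Σ_aligned 1 / (1 + (d_i / d0(L_norm))^2)`` with ``d_i``
    the Cα–Cα distance after applying ``transform`` to A.
    """
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    PA = A.coords if isinstance(A, ProteinStructure) else np.asarray(A, dtype=float)
    PB = B.coords if isinstance(B, ProteinStructure) else np.asarray(B, dtype=float)
    ai = corr.pairs[:, 0]
    bi = corr.pairs[:, 1]
    d = np.linalg.norm(transform.apply(PA[ai]) - PB[bi], axis=1)
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


# ---------------------------------------------------------------------------
# Affine global DP (Gotoh) on a residue-residue score matrix.
# gap_open applies on every gap opening (and on gap-to-gap switches);
# extension is free.  Traceback ties prefer diagonal, then up, then left.

_NEG = -1.0e30


@njit(cache=True)
def _affine_dp(S, gap_open):  # pragma: no cover - exercised via structural_align
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in B: consume A rows ("up")
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in A: consume B cols ("left")
    # pointers: predecessor state 0=M, 1=Ix, 2=Iy (255 = none)
    pM = np.full((n + 1, m + 1), 255, dtype=np.uint8)
    pX = np.full((n + 1, m + 1), 255, dtype=np.uint8)
    pY = np.full((n + 1, m + 1), 255, dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: best predecessor, diagonal move
            best = M[i - 1, j - 1]
            arg = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                arg = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                arg = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = arg
            # up: gap in B
            best = M[i - 1, j] + gap_open
            arg = 0
            if Ix[i - 1, j] > best:
                best = Ix[i - 1, j]
                arg = 1
            if Iy[i - 1, j] + gap_open > best:
                best = Iy[i - 1, j] + gap_open
                arg = 2
            Ix[i, j] = best
            pX[i, j] = arg
            # left: gap in A
            best = M[i, j - 1] + gap_open
            arg = 0
            if Ix[i, j - 1] + gap_open > best:
                best = Ix[i, j - 1] + gap_open
                arg = 1
            if Iy[i, j - 1] > best:
                best = Iy[i, j - 1]
                arg = 2
            Iy[i, j] = best
            pY[i, j] = arg
    # terminal state preference: M > Ix > Iy on ties
    state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best = Ix[n, m]
        state = 1
    if Iy[n, m] > best:
        best = Iy[n, m]
        state = 2
    ai = np.empty(n + m, dtype=np.int64)
    bi = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ai[k] = i - 1
            bi[k] = j - 1
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return ai[:k][::-1].copy(), bi[:k][::-1].copy()


def _evaluate(
    PA: np.ndarray, PB: np.ndarray, ai: np.ndarray, bi: np.ndarray, LA: int, LB: int
) -> tuple[float, float, float, float, tuple[np.ndarray, np.ndarray]]:
    """Superpose on (ai, bi) and score: (tm_ab, tm_ba, tm_sym, rmsd, (R, t))."""
    R, t, rmsd = _kabsch_raw(PA[ai], PB[bi])
    d = np.linalg.norm(PA[ai] @ R.T + t - PB[bi], axis=1)
    tm_a = float(np.sum(1.0 / (1.0 + (d / tm_d0(LA)) ** 2)) / LA)
    tm_b = float(np.sum(1.0 / (1.0 + (d / tm_d0(LB)) ** 2)) / LB)
    return tm_a, tm_b, 0.5 * (tm_a + tm_b), rmsd, (R, t)


def structural_align(
    A: ProteinStructure,
    B: ProteinStructure,
    gap_open: float = -0.6,
    max_iter: int = 30,
    stride: int = 1,
    max_refined: int = 5,
) -> AlignmentResult:
    """Sequence-independent structural alignment of two Cα traces.

    Candidate correspondences are seeded by gapless threading of the
    shorter chain onto the longer at offsets ``0, stride, 2*stride, ...``.
    Every seed is scored by superposition; the ``max_refined`` best are
    refined by iterating superposition and global affine DP on the
    TM-score terms until the correspondence stops changing (at most
    ``max_iter`` rounds).  The result is the correspondence with the
    highest symmetric TM-score seen anywhere in the search; its RMSD and
    transform come from a final least-squares superposition.

    The computation is symmetric by construction: the pair is reordered
    internally to a canonical (length, id) order, so
    ``structural_align(A, B)`` and ``structural_align(B, A)`` return
    identical scores.
    """
    if A.length < 5 or B.length < 5:
        raise ValueError("structural alignment requires structures of at least 5 residues")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    swapped = (B.length, B.id) < (A.length, A.id)
    X, Y = (B, A) if swapped else (A, B)  # canonical order: X <= Y by (length, id)
    PX, PY = X.coords, Y.coords
    LX, LY = X.length, Y.length
    d0_dp = tm_d0(min(LX, LY))

    # seed offsets: gapless threading of X (the shorter) onto Y
    idx = np.arange(LX)
    seeds = []
    for off in range(0, LY - LX + 1, stride):
        seeds.append((idx, idx + off))

    def score_xy(ai: np.ndarray, bi: np.ndarray):
        return _evaluate(PX, PY, ai, bi, LX, LY)

    seed_scores = [score_xy(ai, bi)[2] for ai, bi in seeds]
    order = sorted(range(len(seeds)), key=lambda k: (-seed_scores[k], k))
    refine = order[: max(1, max_refined)]

    best_tm = -1.0
    best_pair: tuple[np.ndarray, np.ndarray] | None = None
    for k in refine:
        ai, bi = seeds[k]
        if seed_scores[k] > best_tm:
            best_tm, best_pair = seed_scores[k], (ai, bi)
        seen = {(ai.tobytes(), bi.tobytes())}
        for _ in range(max_iter):
            R, t, _ = _kabsch_raw(PX[ai], PY[bi])
            D = cdist(PX @ R.T + t, PY)
            S = 1.0 / (1.0 + (D / d0_dp) ** 2)
            new_ai, new_bi = _affine_dp(S, gap_open)
            if len(new_ai) < 3:
                break
            tm = score_xy(new_ai, new_bi)[2]
            if tm > best_tm:
                best_tm, best_pair = tm, (new_ai, new_bi)
            key = (new_ai.tobytes(), new_bi.tobytes())
            if key in seen:  # converged or entered a cycle
                break
            seen.add(key)
            ai, bi = new_ai, new_bi

    assert best_pair is not None
    xi, yi = best_pair
    if swapped:
        a_idx, b_idx = yi, xi
    else:
        a_idx, b_idx = xi, yi
    tm_x, tm_y, tm_sym, rmsd, (R_xy, t_xy) = _evaluate(PX, PY, xi, yi, LX, LY)
    if swapped:
        tm_ab, tm_ba = tm_y, tm_x
        # transform mapped A onto B in canonical (X, Y) = (B, A) order; invert
        transform = RigidTransform(R_xy.T, -R_xy.T @ t_xy)
    else:
        tm_ab, tm_ba = tm_x, tm_y
        transform = RigidTransform(R_xy, t_xy)
    corr = Correspondence(np.stack([a_idx, b_idx], axis=1))
    return AlignmentResult(
        correspondence=corr,
        transform=transform,
        tm_ab=tm_ab,
        tm_ba=tm_ba,
        tm_sym=tm_sym,
        rmsd=rmsd,
        n_aligned=len(corr),
    )
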