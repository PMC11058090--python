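"""Gaussian non-negative matrix factorization of gait-cycle EMG matrices.

Each time-normalized cycle matrix V (muscles x points) is approximated as
V ~= V_R = M P, where M (muscles x p) holds the time-invariant muscle
weights and P (p x points) the time-dependent activation patterns of p
muscle synergies. The factorization minimizes the squared Frobenius
reconstruction error with the classical multiplicative update rules, which
keep every entry non-negative and never increase the error.

Robustness and rank selection follow common practice for this family of
analyses: the factorization is repeated from random initializations and the
repetitions are component-matched and averaged; the rank is the smallest p
from which the R^2-versus-rank curve is statistically flat-linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SynergySet",
    "nmf_factorize",
    "r_squared",
    "average_repetitions",
    "select_rank",
]

_EPS = 1e-12


@dataclass
class SynergySet:
    """Factors of one cycle: weights M (m x p) and patterns P (p x n).

    Each pattern row is max-normalized to 1 with the compensating scale
    folded into the matching weight column, so M @ P reproduces the
    unnormalized reconstruction. ``r_squared`` is the coefficient of
    determination of that reconstruction against the source matrix.
    """

    M: np.ndarray
    P: np.ndarray
    rank: int
    r_squared: float
    n_repetitions: int = 1
    cycle_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.M.shape[1] != self.rank or self.P.shape[0] != self.rank:
            raise ValueError("factor shapes inconsistent with rank")
        if np.min(self.M) < 0 or np.min(self.P) < 0:
            raise ValueError("synergy factors must be non-negative")
        if self.r_squared > 1 + 1e-12:
            raise ValueError(f"r_squared cannot exceed 1, got {self.r_squared}")

    def reconstruction(self) -> np.ndarray:
        return self.M @ self.P

    def weights_normalized(self) -> np.ndarray:
        """Muscle weights with each column max-normalized to 1 (for display)."""
        scale = self.M.max(axis=0)
        scale[scale == 0] = 1.0
        return self.M / scale


def r_squared(V: np.ndarray, V_R: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST, SST around the grand mean."""
    V = np.asarray(V, dtype=float)
    V_R = np.asarray(V_R, dtype=float)
    if V.shape != V_R.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {V_R.shape}")
    sst = float(np.sum((V - V.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for a constant matrix (SST = 0)")
    sse = float(np.sum((V - V_R) ** 2))
    return 1.0 - sse / sst


def _normalize_rows(M: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = P.max(axis=1)
    scale[scale == 0] = 1.0
    return M * scale, P / scale[:, None]


def nmf_factorize(
    V,
    rank: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
    window: int = 20,
    return_history: bool = False,
):
    """One multiplicative-update factorization from a seeded random start.

    Initial factors are uniform on (0, 1]. Iteration stops when R^2 improved
    by less than ``tol`` (default 0.01 percentage points) over the last
    ``window`` iterations, or at ``max_iter``. With ``return_history`` the
    per-iteration squared Frobenius errors are returned alongside the result
    (they are non-increasing, a property of the update rules).
    """
    A = getattr(V, "V", V)
    A = np.asarray(A, dtype=float)
    cycle_index = getattr(V, "cycle_index", 0)
    if A.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if np.min(A) < 0:
        raise ValueError("V must be non-negative for NMF")
    m, n = A.shape
    if not (1 <= rank <= m):
        raise ValueError(f"rank must be in [1, {m}], got {rank}")
    sst = float(np.sum((A - A.mean()) ** 2))
    if sst == 0:
        raise ValueError("cannot factorize a constant matrix")

    rng = np.random.default_rng(seed)
    M = 1.0 - rng.random((m, rank))  # uniform on (0, 1]
    P = 1.0 - rng.random((rank, n))

    history = []
    r2_hist = []
    for it in range(max_iter):
        P *= (M.T @ A) / (M.T @ M @ P + _EPS)
        M *= (A @ P.T) / (M @ (P @ P.T) + _EPS)
        err = float(np.sum((A - M @ P) ** 2))
        history.append(err)
        r2_hist.append(1.0 - err / sst)
        if it >= window and r2_hist[-1] - r2_hist[-1 - window] < tol:
            break

    M, P = _normalize_rows(M, P)
    result = SynergySet(
        M=M,
        P=P,
        rank=rank,
        r_squared=r2_hist[-1],
        n_repetitions=1,
        cycle_index=cycle_index,
        seed=seed,
    )
    if return_history:
        return result, np.asarray(history)
    return result


def _match_columns(M_ref: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Permutation aligning columns of M to M_ref by maximal cosine similarity.

    Optimal one-to-one assignment for small ranks; greedy for rank > 8.
    """
    ref = M_ref / (np.linalg.norm(M_ref, axis=0, keepdims=True) + _EPS)
    cur = M / (np.linalg.norm(M, axis=0, keepdims=True) + _EPS)
    sim = ref.T @ cur
    p = sim.shape[0]
    if p <= 8:
        _, cols = linear_sum_assignment(-sim)
        return cols
    perm = np.full(p, -1)
    s = sim.copy()
    for _ in range(p):
        i, j = np.unravel_index(np.argmax(s), s.shape)
        perm[i] = j
        s[i, :] = -np.inf
        s[:, j] = -np.inf
    return perm


def average_repetitions(
    V,
    rank: int,
    n_rep: int = 20,
    seed: int = 0,
    **nmf_kwargs,
) -> SynergySet:
    """Repeat the factorization ``n_rep`` times and average matched factors.

    Repetitions are seeded independently from ``seed``; components of each
    repetition are aligned to the first repetition by optimal one-to-one
    assignment on the cosine similarity of muscle-weight columns before
    averaging, resolving the permutation ambiguity of NMF. The reported R^2
    is that of the averaged reconstruction.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    A = getattr(V, "V", V)
    cycle_index = getattr(V, "cycle_index", 0)
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_rep)
    reps = [nmf_factorize(V, rank, seed=int(s), **nmf_kwargs) for s in rep_seeds]
    M_sum = reps[0].M.copy()
    P_sum = reps[0].P.copy()
    for rep in reps[1:]:
        perm = _match_columns(reps[0].M, rep.M)
        M_sum += rep.M[:, perm]
        P_sum += rep.P[perm, :]
    M_avg, P_avg = _normalize_rows(M_sum / n_rep, P_sum / n_rep)
    return SynergySet(
        M=M_avg,
        P=P_avg,
        rank=rank,
        r_squared=r_squared(np.asarray(A, dtype=float), M_avg @ P_avg),
        n_repetitions=n_rep,
        cycle_index=cycle_index,
        seed=seed,
    )


def _flat_from(curve: np.ndarray, start: int) -> float:
    """Mean squared residual of an OLS line fit to curve[start:]."""
    y = curve[start:]
    if y.size <= 2:
        return 0.0
    x = np.arange(y.size, dtype=float)
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(np.mean(resid**2))


def select_rank(
    V,
    max_rank: int = 10,
    n_rep: int = 10,
    seed: int = 0,
    flat_mse: float = 1e-4,
    **nmf_kwargs,
) -> tuple[int, np.ndarray]:
    """Choose the factorization rank from the R^2-versus-rank curve.

    For each candidate rank 1..max_rank the best R^2 over ``n_rep`` seeded
    repetitions is recorded; the selected rank is the smallest one from which
    the remaining curve fits a least-squares line with mean squared residual
    below ``flat_mse`` — the point where adding synergies no longer improves
    the reconstruction beyond a linear trend. Returns (rank, R^2 curve).
    """
    A = getattr(V, "V", V)
    A = np.asarray(A, dtype=float)
    max_rank = min(max_rank, A.shape[0])
    rank_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=max_rank)
    curve = np.empty(max_rank)
    for r in range(1, max_rank + 1):
        rep_seeds = np.random.default_rng(int(rank_seeds[r - 1])).integers(
            0, 2**31 - 1, size=n_rep
        )
        curve[r - 1] = max(
            nmf_factorize(V, r, seed=int(s), **nmf_kwargs).r_squared
            for s in rep_seeds
        )
    for r in range(1, max_rank + 1):
        if _flat_from(curve, r - 1) < flat_mse:
            return r, curve
    return max_rank, curve
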