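"""Non-negative matrix factorization with multiplicative updates.

The conditioned activation matrix V (m muscles x n time points) is
approximated as V ≈ V_R = W·H with W (m x r, time-invariant motor modules)
and H (r x n, time-dependent motor primitives) elementwise nonnegative. The
factors are fit by the classical Gaussian (squared-error) multiplicative
update rules, alternating per iteration

    H <- H ∘ (WᵀV) / (WᵀW H)        then        W <- W ∘ (V Hᵀ) / (W H Hᵀ)

with the W update already using the fresh H. Reconstruction quality is the
coefficient of determination R² between V and W·H; iteration stops when the
spread of R² over the last 20 iterations falls below 0.01% of its current
value. Each rank is fit from several random restarts and the highest-R²
solution kept.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError

#: Denominator floor guarding the multiplicative updates against division by
#: zero (the updates themselves never produce negatives).
EPS = 1e-12
#: Convergence: relative R² spread over this many trailing iterations.
CONV_WINDOW = 20
CONV_TOL = 1e-4  # 0.01 %
MAX_ITER_DEFAULT = 1000


class NumericalError(ArithmeticError):
    """NaN or Inf appeared during the iteration."""


@dataclass
class SynergySet:
    """One factorization result: modules W, primitives H and fit metadata."""

    W: np.ndarray          # (m, r) nonnegative muscle weightings
    H: np.ndarray          # (r, n) nonnegative activation coefficients
    r: int
    r_squared: float
    iterations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValidationError("W and H must be nonnegative")
        if self.W.shape[1] != self.r or self.H.shape[0] != self.r:
            raise ValidationError("rank inconsistent with factor shapes")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ModelOrderCurve:
    """Best-of-restarts R² for each candidate number of synergies."""

    r_values: np.ndarray
    best_r2: np.ndarray

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=int)
        self.best_r2 = np.asarray(self.best_r2, dtype=float)
        if self.r_values.shape != self.best_r2.shape:
            raise ValidationError("r_values and best_r2 must have equal length")
        if np.any((self.best_r2 < 0) | (self.best_r2 > 1)):
            raise ValidationError("R² values must lie in [0, 1]")

    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.r_values.tolist(), self.best_r2.tolist()))


def r_squared(V: np.ndarray, V_R: np.ndarray) -> float:
    """Coefficient of determination between data and reconstruction.

    1 - SSE/SST over all matrix entries, with SST taken about the grand mean
    of V. Raises on a constant V (SST = 0).
    """
    V = np.asarray(V, dtype=float)
    V_R = np.asarray(V_R, dtype=float)
    if V.shape != V_R.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {V_R.shape}")
    sst = float(np.sum((V - V.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("V is constant: R² undefined (SST = 0)")
    sse = float(np.sum((V - V_R) ** 2))
    return 1.0 - sse / sst


def nmf_factorize(V: np.ndarray, r: int, seed: int | None = None,
                  max_iter: int = MAX_ITER_DEFAULT,
                  conv_window: int = CONV_WINDOW,
                  conv_tol: float = CONV_TOL) -> SynergySet:
    """Factorize V into r synergies from one seeded random start.

    W and H start i.i.d. uniform on (0, 1]. Per iteration H is updated first,
    then W using the updated H; R² is evaluated once per iteration after both
    updates. Converges when max-min of the last ``conv_window`` R² values is
    below ``conv_tol`` (relative to the current R²), else stops at
    ``max_iter``.
    """
    V = np.asarray(V, dtype=float)
    m, n = V.shape
    if not 1 <= r <= m:
        raise ValueError(f"rank r={r} must satisfy 1 <= r <= {m} (muscle count)")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    rng = np.random.default_rng(seed)
    # 1 - U[0,1) lies in (0, 1]: strictly positive so no entry is absorbed at 0
    W = 1.0 - rng.random((m, r))
    H = 1.0 - rng.random((r, n))
    history: deque[float] = deque(maxlen=conv_window)
    r2 = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / np.maximum((W.T @ W) @ H, EPS)
        W *= (V @ H.T) / np.maximum(W @ (H @ H.T), EPS)
        if not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise NumericalError(f"non-finite factor entries at iteration {it}")
        r2 = r_squared(V, W @ H)
        history.append(r2)
        if len(history) == conv_window and \
                (max(history) - min(history)) < conv_tol * abs(r2):
            break
    return SynergySet(W=W, H=H, r=r, r_squared=r2, iterations=it, seed=seed)


def rank_sweep(V: np.ndarray, r_max: int = 10, restarts: int = 10,
               seed: int = 0, max_iter: int = MAX_ITER_DEFAULT,
               conv_window: int = CONV_WINDOW,
               conv_tol: float = CONV_TOL
               ) -> tuple[ModelOrderCurve, list[SynergySet]]:
    """Fit every rank 1..r_max with seeded restarts; keep the best per rank.

    For each rank, ``restarts`` factorizations are run from fresh random
    initial matrices (restart j uses seed ``seed + j``) and the solution with
    the highest R² is retained.
    """
    V = np.asarray(V, dtype=float)
    m = V.shape[0]
    if not 1 <= r_max < m:
        raise ValueError(f"r_max={r_max} must satisfy 1 <= r_max < {m}")
    best: list[SynergySet] = []
    for r in range(1, r_max + 1):
        sols = [nmf_factorize(V, r, seed=seed + j, max_iter=max_iter,
                              conv_window=conv_window, conv_tol=conv_tol)
                for j in range(restarts)]
        best.append(max(sols, key=lambda s: s.r_squared))
    curve = ModelOrderCurve(np.arange(1, r_max + 1),
                            np.clip([s.r_squared for s in best], 0.0, 1.0))
    return curve, best
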