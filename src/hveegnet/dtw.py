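"""Dynamic time warping: exact scores, warping paths and a smooth training loss.

The exact algorithm builds the cumulative cost matrix ``W`` with local cost
``|a(i) - b(j)|`` (absolute difference, *not* squared), backtracks the optimal
monotone warping path from corner to corner, and reports either

* ``mode="path-mean"`` (default): the mean of the cumulative ``W`` values read
  along the optimal path, i.e. ``sum_k d(k) / K`` with ``K`` the path length, or
* ``mode="corner"``: the terminal corner cost divided by ``K``.

The two conventions coexist because the literature normalizes DTW scores in
both ways; every result container records which one produced it.

The smooth variant (:func:`soft_dtw`) replaces the hard minimum of the
recurrence with a log-sum-exp soft minimum at temperature ``gamma`` (Cuturi &
Blondel's relaxation), which is differentiable everywhere and converges to the
exact corner cost as ``gamma -> 0+``.  Training uses the *un-normalized*
channel-summed soft score; evaluation uses the normalized exact score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DtwResult",
    "SoftDtwConfig",
    "dtw_cost_matrix",
    "optimal_warping_path",
    "normalized_dtw_score",
    "soft_dtw",
    "soft_dtw_grad",
    "multichannel_dtw",
]


@dataclass
class SoftDtwConfig:
    """Temperature and (optional) band constraint for the smooth DTW loss.

    ``gamma`` is the soft-min temperature in the units of the local cost
    (microvolts here); 1.0 is the training default.  ``bandwidth`` is a
    Sakoe-Chiba half-width used purely as a speed device; ``None`` (default)
    runs the full unconstrained recurrence.
    """

    gamma: float = 1.0
    bandwidth: int | None = None

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"soft-DTW temperature gamma must be > 0, got {self.gamma}")
        if self.bandwidth is not None and self.bandwidth < 1:
            raise ValueError("bandwidth must be a positive integer or None")


@dataclass
class DtwResult:
    """Cost matrix, optimal path and both normalized scores for one pair."""

    W: np.ndarray
    path: list[tuple[int, int]]
    d: np.ndarray
    K: int
    corner_cost: float
    normalized_score: float
    mode: str = "path-mean"
    scores: dict = field(default_factory=dict)  # both normalizations, flagged


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("DTW requires finite sequence values")
    return a, b


@njit(cache=True)
def _accumulate(a, b):  # pragma: no cover - exercised through the wrappers
    n, m = a.shape[0], b.shape[0]
    W = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                W[i, j] = c
            elif i == 0:
                W[i, j] = c + W[i, j - 1]
            elif j == 0:
                W[i, j] = c + W[i - 1, j]
            else:
                best = W[i - 1, j - 1]
                if W[i, j - 1] < best:
                    best = W[i, j - 1]
                if W[i - 1, j] < best:
                    best = W[i - 1, j]
                W[i, j] = c + best
    return W


def dtw_cost_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cumulative cost matrix with local cost ``|a(i)-b(j)|``.

    ``W[0, 0] = |a(0)-b(0)|``; interior cells add the minimum of the three
    predecessor cells; boundary cells use the only available predecessor.
    """
    a, b = _check_pair(a, b)
    return _accumulate(a, b)


def optimal_warping_path(W: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray, int]:
    """Backtrack the minimum-cost monotone path through ``W``.

    Returns ``(path, d, K)`` where ``path`` runs from ``(0, 0)`` to the
    terminal corner, ``d`` holds the ``W`` values along it and ``K = len(d)``.
    Ties are broken deterministically: diagonal predecessor first, then the
    predecessor in the second series (left), then the first (down).
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.size == 0:
        raise ValueError("W must be a non-empty 2-D cost matrix")
    i, j = W.shape[0] - 1, W.shape[1] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, left, down = W[i - 1, j - 1], W[i, j - 1], W[i - 1, j]
            if diag <= left and diag <= down:
                i, j = i - 1, j - 1
            elif left <= down:
                j -= 1
            else:
                i -= 1
        rev.append((i, j))
    path = rev[::-1]
    d = np.array([W[p] for p in path])
    return path, d, len(d)


def dtw(a: np.ndarray, b: np.ndarray, mode: str = "path-mean") -> DtwResult:
    """Full exact-DTW result for one pair of sequences."""
    if mode not in ("path-mean", "corner"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    W = dtw_cost_matrix(a, b)
    path, d, K = optimal_warping_path(W)
    corner = float(W[-1, -1])
    scores = {"path-mean": float(d.mean()), "corner": corner / K}
    return DtwResult(W=W, path=path, d=d, K=K, corner_cost=corner,
                     normalized_score=scores[mode], mode=mode, scores=scores)


def normalized_dtw_score(a: np.ndarray, b: np.ndarray, mode: str = "path-mean") -> float:
    """Normalized DTW score between two sequences (see module docstring)."""
    return dtw(a, b, mode=mode).normalized_score


@njit(cache=True)
def _soft_forward(cost, gamma, band):  # pragma: no cover
    n, m = cost.shape
    inf = np.inf
    R = np.full((n + 1, m + 1), inf)
    R[0, 0] = 0.0
    for i in range(1, n + 1):
        lo, hi = 1, m
        if band > 0:
            lo = max(1, i - band)
            hi = min(m, i + band)
        for j in range(lo, hi + 1):
            r0 = -R[i - 1, j - 1] / gamma
            r1 = -R[i - 1, j] / gamma
            r2 = -R[i, j - 1] / gamma
            rmax = max(r0, max(r1, r2))
            if rmax == -inf:
                softmin = inf
            else:
                rsum = np.exp(r0 - rmax) + np.exp(r1 - rmax) + np.exp(r2 - rmax)
                softmin = -gamma * (np.log(rsum) + rmax)
            R[i, j] = cost[i - 1, j - 1] + softmin
    return R


@njit(cache=True)
def _soft_backward(cost, R, gamma, band):  # pragma: no cover
    n, m = cost.shape
    E = np.zeros((n + 2, m + 2))
    E[n + 1, m + 1] = 1.0
    Rp = np.full((n + 2, m + 2), -np.inf)
    for i in range(n + 1):
        for j in range(m + 1):
            Rp[i, j] = R[i, j]
    # unreached cells (outside a band) must not contribute: mark them -inf
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if np.isinf(Rp[i, j]):
                Rp[i, j] = -np.inf
    Rp[n + 1, m + 1] = R[n, m]
    C = np.zeros((n + 2, m + 2))
    C[1:n + 1, 1:m + 1] = cost
    for i in range(n, 0, -1):
        for j in range(m, 0, -1):
            if Rp[i, j] == -np.inf:
                continue
            a0 = np.exp((Rp[i + 1, j] - Rp[i, j] - C[i + 1, j]) / gamma)
            b0 = np.exp((Rp[i, j + 1] - Rp[i, j] - C[i, j + 1]) / gamma)
            c0 = np.exp((Rp[i + 1, j + 1] - Rp[i, j] - C[i + 1, j + 1]) / gamma)
            E[i, j] = E[i + 1, j] * a0 + E[i, j + 1] * b0 + E[i + 1, j + 1] * c0
    return E[1:n + 1, 1:m + 1]


def soft_dtw(a: np.ndarray, b: np.ndarray, cfg: SoftDtwConfig | None = None) -> float:
    """Smooth (soft-min) DTW value; converges to the exact corner cost as gamma->0."""
    cfg = cfg or SoftDtwConfig()
    a, b = _check_pair(a, b)
    cost = np.abs(a[:, None] - b[None, :])
    band = cfg.bandwidth if cfg.bandwidth is not None else 0
    R = _soft_forward(cost, cfg.gamma, band)
    return float(R[-1, -1])


def soft_dtw_grad(a: np.ndarray, b: np.ndarray, cfg: SoftDtwConfig | None = None
                  ) -> tuple[float, np.ndarray]:
    """Soft-DTW value and its gradient with respect to the *first* sequence.

    The gradient flows through the local cost ``|a_i - b_j|`` as
    ``sum_j E_ij * sign(a_i - b_j)`` where ``E`` is the expected alignment
    matrix of the soft-min relaxation.
    """
    cfg = cfg or SoftDtwConfig()
    a, b = _check_pair(a, b)
    diff = a[:, None] - b[None, :]
    cost = np.abs(diff)
    band = cfg.bandwidth if cfg.bandwidth is not None else 0
    R = _soft_forward(cost, cfg.gamma, band)
    E = _soft_backward(cost, R, cfg.gamma, band)
    grad = (E * np.sign(diff)).sum(axis=1)
    return float(R[-1, -1]), grad


def multichannel_dtw(x: np.ndarray, x_hat: np.ndarray, mode: str = "loss-sum",
                     cfg: SoftDtwConfig | None = None,
                     score_mode: str = "path-mean"):
    """Channel-wise DTW between a segment and its reconstruction.

    ``x`` and ``x_hat`` are ``(C, T)`` arrays sharing a shape.  In
    ``"loss-sum"`` mode the *un-normalized* soft-DTW values are summed over
    channels (the training convention); in ``"eval-per-channel"`` mode the
    exact normalized score of every channel is returned as a length-``C``
    vector (the evaluation convention).
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape or x.ndim != 2:
        raise ValueError(f"expected matching (C, T) arrays, got {x.shape} vs {x_hat.shape}")
    if mode == "loss-sum":
        return float(sum(soft_dtw(x[c], x_hat[c], cfg) for c in range(x.shape[0])))
    if mode == "eval-per-channel":
        return np.array([normalized_dtw_score(x[c], x_hat[c], mode=score_mode)
                         for c in range(x.shape[0])])
    raise ValueError(f"unknown mode {mode!r}")
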