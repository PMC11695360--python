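"""Reconstruction-error anomaly detection.

Pipeline: every repetition r and channel c of a dataset is scored with the
normalized DTW between the segment and its posterior-mean reconstruction,
giving an R x C error matrix E per training run; matrices are averaged
across (successful) runs; each repetition is then a point in C-dimensional
error space, its distance to the k-th nearest neighbour is computed
(Euclidean, default k=15 on the benchmark-sized matrix), the ascending
sorted distance curve is thresholded at its knee (Kneedle,
decreasing-sensitivity), and repetitions above the threshold are flagged.

A second diagnostic locates the training *transition point*: the checkpoint
epoch where the mean error curve elbows while the across-run spread is
still small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dtw import multichannel_dtw

__all__ = ["ErrorMatrix", "OutlierReport", "TransitionPoint", "kneedle",
           "compute_error_matrix", "average_error_matrices", "detect_outliers",
           "find_transition_point"]


@dataclass
class ErrorMatrix:
    """R x C matrix of normalized DTW scores for one training run."""

    values: np.ndarray
    run: int = 0
    score_mode: str = "path-mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("error matrix must be 2-D (repetitions x channels)")
        if np.any(self.values < 0):
            raise ValueError("normalized DTW scores are non-negative")


@dataclass
class OutlierReport:
    kth_distances: np.ndarray
    k: int
    threshold: float
    flagged: list[int]
    knee_found: bool
    worst_channel: dict[int, int] = field(default_factory=dict)
    channel_excess: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        r = np.arange(self.kth_distances.size)
        return pd.DataFrame({
            "repetition": r,
            "kth_distance": self.kth_distances,
            "flagged": np.isin(r, self.flagged),
            "worst_channel": [self.worst_channel.get(i, -1) for i in r],
        })


@dataclass
class TransitionPoint:
    epoch: int
    elbow_statistic: np.ndarray
    mean_error: np.ndarray
    std_error: np.ndarray
    outlier_counts: np.ndarray
    epochs: np.ndarray
    note: str = ""


def compute_error_matrix(model, data: np.ndarray, run: int = 0,
                         score_mode: str = "path-mean",
                         stochastic: bool = False, seed: int = 0) -> ErrorMatrix:
    """Score every (repetition, channel) of ``data`` against the model.

    ``data`` is ``(R, 1, C, T)``.  The reconstruction is the posterior-mean
    decode by default, which makes the matrix deterministic for a given
    checkpoint; ``stochastic=True`` samples the latents instead.
    """
    data = np.asarray(data, dtype=np.float64)
    rec = model.forward(data, seed=seed, sample=True) if stochastic \
        else model.reconstruct(data)
    rows = [multichannel_dtw(data[i, 0], rec[i, 0], mode="eval-per-channel",
                             score_mode=score_mode)
            for i in range(data.shape[0])]
    return ErrorMatrix(values=np.vstack(rows), run=run, score_mode=score_mode)


def average_error_matrices(matrices: list[ErrorMatrix]) -> ErrorMatrix:
    """Elementwise mean across runs (unsuccessful runs must be pre-filtered)."""
    if not matrices:
        raise ValueError("at least one error matrix is required")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"error matrices disagree in shape: {shapes}")
    modes = {m.score_mode for m in matrices}
    if len(modes) != 1:
        raise ValueError("cannot average matrices with mixed score modes")
    return ErrorMatrix(values=np.mean([m.values for m in matrices], axis=0),
                       run=-1, score_mode=matrices[0].score_mode)


def kneedle(y: np.ndarray, sensitivity: float = 1.0, curve: str = "convex",
            direction: str = "increasing") -> int | None:
    """Kneedle knee/elbow locator on an ordered curve (index into ``y``).

    The curve is min-max normalized; for a convex increasing curve the elbow
    is the largest local maximum of ``x_n - y_n`` that survives the
    decreasing-sensitivity test.  Returns ``None`` when the curve carries no
    usable structure (constant, or no interior extremum).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 3:
        return None
    rng_y = y.max() - y.min()
    if rng_y <= 0:
        return None
    x_n = np.linspace(0.0, 1.0, n)
    y_n = (y - y.min()) / rng_y
    if direction == "decreasing":
        y_n = y_n[::-1]
    if curve == "convex":
        diff = x_n - y_n
    elif curve == "concave":
        diff = y_n - x_n
    else:
        raise ValueError(f"unknown curve type {curve!r}")
    # local maxima of the difference curve
    maxima = [i for i in range(1, n - 1)
              if diff[i] >= diff[i - 1] and diff[i] >= diff[i + 1]]
    if not maxima:
        return None
    threshold_drop = sensitivity * np.abs(np.diff(x_n)).mean()
    for i in maxima:
        t = diff[i] - threshold_drop
        j = i + 1
        while j < n:
            if diff[j] > diff[i]:  # a later, larger maximum supersedes this one
                break
            if diff[j] < t:
                idx = i if direction == "increasing" else n - 1 - i
                return int(idx)
            j += 1
        if j == n:
            idx = i if direction == "increasing" else n - 1 - i
            return int(idx)
    return None


def detect_outliers(avg: ErrorMatrix, k: int = 15, sensitivity: float = 1.0,
                    excess_factor: float = 2.0) -> OutlierReport:
    """kNN + knee outlier identification on the averaged error matrix.

    Each repetition is a C-dimensional point; its Euclidean distance to the
    k-th nearest *other* repetition is computed, distances are sorted
    ascending and thresholded at the Kneedle knee.  Repetitions whose
    distance exceeds the threshold are flagged.  For each flagged repetition
    the channels whose error exceeds ``excess_factor`` times the row median
    are reported, the largest as ``worst_channel``.
    """
    E = avg.values
    R = E.shape[0]
    if R <= k:
        raise ValueError(f"need more repetitions ({R}) than neighbours (k={k})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)  # +1: drop the self-match
    dist, _ = nn.kneighbors(E)
    kth = dist[:, k]
    order = np.argsort(kth, kind="stable")
    knee = kneedle(kth[order], sensitivity=sensitivity,
                   curve="convex", direction="increasing")
    if knee is None:
        warnings.warn("no knee found in the sorted kth-neighbour distance curve; "
                      "flagging no outliers", stacklevel=2)
        return OutlierReport(kth_distances=kth, k=k, threshold=float("inf"),
                             flagged=[], knee_found=False)
    threshold = float(kth[order][knee])
    flagged = sorted(int(r) for r in np.where(kth > threshold)[0])
    worst, excess = {}, {}
    for r in flagged:
        row = E[r]
        med = np.median(row)
        over = np.where(row > excess_factor * max(med, 1e-300))[0]
        excess[r] = over
        worst[r] = int(np.argmax(row))
    return OutlierReport(kth_distances=kth, k=k, threshold=threshold,
                         flagged=flagged, knee_found=True,
                         worst_channel=worst, channel_excess=excess)


def find_transition_point(epochs: np.ndarray, mean_error: np.ndarray,
                          std_error: np.ndarray,
                          outlier_counts: np.ndarray | None = None
                          ) -> TransitionPoint:
    """Locate the elbow of the mean-error-vs-epoch curve.

    Checkpoints are admissible when the across-run standard deviation lies
    at or below its median over checkpoints; among admissible checkpoints
    the Kneedle elbow statistic of the (decreasing, convex) mean curve is
    maximized, ties resolved toward the earlier epoch.  Degenerate curves
    fall back with a warning: strictly linear -> last checkpoint, constant
    -> first checkpoint.
    """
    epochs = np.asarray(epochs, dtype=int)
    mean_error = np.asarray(mean_error, dtype=np.float64)
    std_error = np.asarray(std_error, dtype=np.float64)
    if outlier_counts is None:
        outlier_counts = np.zeros_like(epochs)
    n = epochs.size
    if n < 4:
        raise ValueError("transition-point analysis needs at least 4 checkpoints")
    rng_y = mean_error.max() - mean_error.min()
    base = dict(mean_error=mean_error, std_error=std_error,
                outlier_counts=np.asarray(outlier_counts), epochs=epochs)
    if rng_y <= 0:
        warnings.warn("constant mean-error curve: no transition structure; "
                      "returning the first checkpoint", stacklevel=2)
        return TransitionPoint(epoch=int(epochs[0]), elbow_statistic=np.zeros(n),
                               note="constant-curve", **base)
    x_n = (epochs - epochs.min()) / (epochs.max() - epochs.min())
    y_n = (mean_error - mean_error.min()) / rng_y
    # elbow statistic for a decreasing convex curve: distance below the chord
    stat = (1.0 - x_n) - y_n
    if np.allclose(stat, 0.0, atol=1e-9):
        warnings.warn("mean-error curve is linear: no elbow; returning the "
                      "last checkpoint", stacklevel=2)
        return TransitionPoint(epoch=int(epochs[-1]), elbow_statistic=stat,
                               note="linear-curve", **base)
    admissible = std_error <= np.median(std_error)
    if not admissible.any():
        admissible = np.ones(n, dtype=bool)
    masked = np.where(admissible, stat, -np.inf)
    best = int(np.argmax(masked))  # argmax takes the earliest on ties
    return TransitionPoint(epoch=int(epochs[best]), elbow_statistic=stat, **base)
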