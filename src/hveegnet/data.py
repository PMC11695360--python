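"""Dataset handling: segmentation, session splits, Welch spectra,
reconstruction-error aggregation and the HDF5 container.

The split protocol mirrors the benchmark convention: the first half of the
trials (the first recording session) is the training pool and the second
half the test set; 10% of the pool (floor) is drawn as validation with a
seed-controlled shuffle, the remainder trains the model.  For the
benchmark-sized 576 trials this yields 260 training, 28 validation and 288
test segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.signal import welch as _welch
from scipy.signal.windows import hann

from .synthetic import SpectralProfile, SyntheticDataset

__all__ = ["SegmentedDataset", "ReconstructionSummary", "segment_trials",
           "split_dataset", "welch_psd", "summarize_reconstruction",
           "save_dataset", "load_dataset"]


@dataclass
class SegmentedDataset:
    segments: np.ndarray          # (R, C, T)
    fs: float
    window: tuple[float, float]   # seconds, half-open [start, end)

    def batch(self) -> np.ndarray:
        return self.segments[:, None]


@dataclass
class ReconstructionSummary:
    per_subject: pd.DataFrame     # columns: subject, mean, std
    grand_average: float
    grand_std: float


def segment_trials(trials: np.ndarray, fs: float,
                   window: tuple[float, float] = (2.0, 6.0)) -> SegmentedDataset:
    """Cut the task-active window out of full-length trials.

    ``trials`` is ``(R, C, T_full)``; the default 2-6 s window at 250 Hz
    yields 1000-sample segments.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.ndim != 3:
        raise ValueError("trials must be (repetitions, channels, time)")
    start, end = window
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    if i0 < 0 or i1 > trials.shape[-1] or i0 >= i1:
        raise ValueError(
            f"window [{start}, {end}) s = samples [{i0}, {i1}) does not fit "
            f"trials of length {trials.shape[-1]}")
    return SegmentedDataset(segments=trials[..., i0:i1], fs=fs, window=window)


def split_dataset(n_trials: int, validation_fraction: float = 0.10,
                  seed: int = 0) -> pd.Series:
    """Session-ordered 50/50 train/test split with a seeded validation draw.

    Returns a length-``n_trials`` Series of labels in {train, validation,
    test}.  The first half of the trials forms the training pool; validation
    holds ``floor(fraction * pool)`` members drawn by a seed-controlled
    shuffle of the pool.
    """
    if n_trials < 10:
        raise ValueError("too few trials to split meaningfully")
    half = n_trials // 2
    labels = np.array(["train"] * half + ["test"] * (n_trials - half), dtype=object)
    n_val = int(np.floor(validation_fraction * half))
    rng = np.random.default_rng(seed)
    val_idx = rng.permutation(half)[:n_val]
    labels[val_idx] = "validation"
    return pd.Series(labels, name="split")


def welch_psd(x: np.ndarray, fs: float, nperseg: int = 500,
              noverlap: int = 250) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram with a Hann window (defaults: 500-point window,
    250-point overlap — the evaluation convention at 250 Hz)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"segment of length {x.shape[-1]} is shorter than the "
            f"{nperseg}-point window")
    freqs, power = _welch(x, fs=fs, window=hann(nperseg), noverlap=noverlap)
    return freqs, power


def summarize_reconstruction(matrices: dict[int, np.ndarray]) -> ReconstructionSummary:
    """Table-style aggregation of per-subject averaged error matrices.

    Per subject: mean over all (repetition, channel) entries; the standard
    deviation is taken over the R repetition-means only.  Grand statistics
    are the mean and standard deviation across the per-subject means.
    """
    if not matrices:
        raise ValueError("at least one subject matrix is required")
    rows = []
    for subject, E in sorted(matrices.items()):
        E = np.asarray(E, dtype=np.float64)
        if E.size == 0:
            raise ValueError(f"empty error matrix for subject {subject}")
        rep_means = E.mean(axis=1)
        rows.append({"subject": subject, "mean": float(E.mean()),
                     "std": float(rep_means.std(ddof=0))})
    per_subject = pd.DataFrame(rows)
    return ReconstructionSummary(
        per_subject=per_subject,
        grand_average=float(per_subject["mean"].mean()),
        grand_std=float(per_subject["mean"].std(ddof=0)))


def save_dataset(dataset: SyntheticDataset, path) -> None:
    """HDF5 layout: /data (S x R x C x T float), /ground_truth (CSV-encoded
    table), attributes carrying fs, seed and the spectral profile JSON."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.values)
        gt_csv = dataset.ground_truth.to_csv(index=False)
        f.create_dataset("ground_truth", data=np.bytes_(gt_csv.encode()))
        f.attrs["fs"] = dataset.fs
        f.attrs["seed"] = -1 if dataset.seed is None else dataset.seed
        f.attrs["profile"] = json.dumps(vars(dataset.profile))


def load_dataset(path) -> SyntheticDataset:
    import io

    with h5py.File(path, "r") as f:
        values = f["data"][...]
        gt_raw = bytes(f["ground_truth"][()]).decode()
        gt = pd.read_csv(io.StringIO(gt_raw)) if gt_raw.count("\n") > 1 \
            else pd.DataFrame(columns=["subject", "repetition", "channels",
                                       "kind", "onset", "duration", "magnitude"])
        profile = SpectralProfile(**json.loads(f.attrs["profile"]))
        seed = int(f.attrs["seed"])
        return SyntheticDataset(values=values, fs=float(f.attrs["fs"]),
                                profile=profile, ground_truth=gt,
                                seed=None if seed == -1 else seed)
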