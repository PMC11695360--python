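"""Training protocol: Adam + exponential LR decay, multi-run repetition with
per-run seeds, per-epoch bookkeeping and screening of unsuccessful runs.

One *run* trains a freshly initialized model on a seed-specific
train/validation shuffle.  The reconstruction term of the loss is the
un-normalized channel-summed soft-DTW; the validation metric logged each
epoch is the *normalized* channel-mean exact DTW of the posterior-mean
reconstruction (the evaluation convention).  Runs whose loss becomes
non-finite, or ends above its starting value, are flagged unsuccessful and
excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .dtw import SoftDtwConfig, multichannel_dtw
from .losses import kl_graph
from .models import build_model
from .nn import Adam, Context

__all__ = ["TrainingConfig", "TrainingHistory", "RunOutcome", "train",
           "run_protocol", "screen_runs", "restore_snapshot"]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run (defaults follow the reference
    protocol: batch 30, lr 0.01, 80 epochs, exponential decay gamma=0.999,
    20 runs)."""

    batch_size: int = 30
    learning_rate: float = 0.01
    epochs: int = 80
    lr_gamma: float = 0.999
    runs: int = 20
    kl_weight: float = 1.0
    dtw_gamma: float = 1.0          # soft-DTW temperature
    checkpoint_every: int = 5        # epoch cadence for snapshots (0 disables)
    validation_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not (0 < self.lr_gamma <= 1):
            raise ValueError("lr_gamma must lie in (0, 1]")


@dataclass
class RunOutcome:
    success: bool
    failure_reason: str = "none"  # none | non_finite_loss | non_decreasing_loss

    def __post_init__(self) -> None:
        if self.success != (self.failure_reason == "none"):
            raise ValueError("failure_reason must be 'none' iff success")


@dataclass
class TrainingHistory:
    """Per-epoch loss traces of one run plus parameter snapshots."""

    seed: int
    epochs: list[int] = field(default_factory=list)
    train_l_vae: list[float] = field(default_factory=list)
    train_l_kl: list[float] = field(default_factory=list)
    train_l_r: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    outcome: RunOutcome = field(default_factory=lambda: RunOutcome(True))
    snapshots: list[tuple[int, list, list]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs, "train_l_vae": self.train_l_vae,
            "train_l_kl": self.train_l_kl, "train_l_r": self.train_l_r,
            "val_score": self.val_score, "lr": self.lr,
            "seed": self.seed,
        })


def _snapshot(model) -> tuple[list, list]:
    params = [p.data.copy() for p in model.parameters()]
    stats = [(bn.running_mean.copy(), bn.running_var.copy())
             for bn in model.batchnorms()]
    return params, stats


def restore_snapshot(model, params: list, stats: list) -> None:
    for p, saved in zip(model.parameters(), params):
        p.data[...] = saved
    for bn, (rm, rv) in zip(model.batchnorms(), stats):
        bn.running_mean[...] = rm
        bn.running_var[...] = rv


def _validation_score(model, val_x: np.ndarray) -> float:
    """Normalized channel-mean DTW of the posterior-mean reconstruction."""
    if val_x.shape[0] == 0:
        return np.nan
    rec = model.reconstruct(val_x)
    scores = [multichannel_dtw(val_x[i, 0], rec[i, 0], mode="eval-per-channel").mean()
              for i in range(val_x.shape[0])]
    return float(np.mean(scores))


def train(model, dataset: tuple[np.ndarray, np.ndarray], cfg: TrainingConfig,
          seed: int = 0) -> TrainingHistory:
    """Train ``model`` in place on ``(train_x, val_x)`` arrays of shape
    ``(N, 1, C, T)``.  The seed drives batching order, dropout masks and the
    reparameterization noise; a non-finite loss aborts the run and flags it
    rather than raising."""
    train_x, val_x = (np.asarray(a, dtype=np.float64) for a in dataset)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    dtw_cfg = SoftDtwConfig(gamma=cfg.dtw_gamma)
    hist = TrainingHistory(seed=seed)
    n = train_x.shape[0]
    from .autodiff import soft_dtw_batch  # local import avoids cycle at module load

    for epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.lr_gamma ** epoch
        order = rng.permutation(n)
        ep_vae, ep_kl, ep_r = [], [], []
        for start in range(0, n, cfg.batch_size):
            xb = train_x[order[start:start + cfg.batch_size]]
            ctx = Context(training=True, rng=rng)
            xh, stats = model.forward_graph(Tensor(xb), ctx, sample=True)
            l_r = soft_dtw_batch(xh, xb, dtw_cfg)
            l_kl = kl_graph(stats)
            loss = l_kl * cfg.kl_weight + l_r
            if not np.isfinite(loss.data):
                hist.outcome = RunOutcome(False, "non_finite_loss")
                return hist
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_vae.append(float(l_kl.data * cfg.kl_weight + l_r.data))
            ep_kl.append(float(l_kl.data))
            ep_r.append(float(l_r.data))
        hist.epochs.append(epoch)
        hist.train_l_vae.append(float(np.mean(ep_vae)))
        hist.train_l_kl.append(float(np.mean(ep_kl)))
        hist.train_l_r.append(float(np.mean(ep_r)))
        hist.val_score.append(_validation_score(model, val_x))
        hist.lr.append(opt.lr)
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            params, stats_ = _snapshot(model)
            hist.snapshots.append((epoch + 1, params, stats_))
    if hist.train_l_vae and hist.train_l_vae[-1] > hist.train_l_vae[0]:
        hist.outcome = RunOutcome(False, "non_decreasing_loss")
    return hist


def run_protocol(data: np.ndarray, variant: str, arch_cfg, cfg: TrainingConfig,
                 base_seed: int = 0):
    """Repeat training ``cfg.runs`` times from different seeds.

    ``data`` is the training pool ``(N, 1, C, T)``; every run redraws the
    validation subset (seed-controlled shuffle) and re-initializes the model
    weights, then trains with :func:`train`.  Returns ``(models, histories)``
    for the runs in seed order.
    """
    seeds = [int(s) for s in
             np.random.SeedSequence(base_seed).generate_state(cfg.runs) >> 1]
    models, histories = [], []
    for run_seed in seeds:
        rng = np.random.default_rng(run_seed)
        n = data.shape[0]
        n_val = int(np.floor(cfg.validation_fraction * n))
        order = rng.permutation(n)
        val_x = data[order[:n_val]]
        train_x = data[order[n_val:]]
        model = build_model(arch_cfg, variant, seed=run_seed)
        hist = train(model, (train_x, val_x), cfg, seed=run_seed)
        models.append(model)
        histories.append(hist)
    return models, histories


def screen_runs(histories: list[TrainingHistory]) -> list[RunOutcome]:
    """Flag unsuccessful runs: non-finite losses, or a final training loss
    above the initial one.  Downstream statistics use surviving runs only."""
    if not histories:
        raise ValueError("at least one history is required")
    outcomes = []
    for h in histories:
        vals = np.asarray(h.train_l_vae, dtype=float)
        if h.outcome.failure_reason == "non_finite_loss" or \
                (vals.size and not np.all(np.isfinite(vals))):
            outcomes.append(RunOutcome(False, "non_finite_loss"))
        elif vals.size and vals[-1] > vals[0]:
            outcomes.append(RunOutcome(False, "non_decreasing_loss"))
        else:
            outcomes.append(RunOutcome(True))
    return outcomes
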