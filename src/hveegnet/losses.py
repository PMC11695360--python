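"""VAE training losses: Gaussian KL terms and the DTW reconstruction loss.

The total loss is ``L = kl_weight * L_KL + L_R`` where ``L_R`` is the
channel-summed, batch-averaged *un-normalized* soft-DTW between input and
reconstruction, and ``L_KL`` the closed-form divergence between the
diagonal-Gaussian posterior(s) and the standard-normal prior,

    KL = 1/2 * sum_i (sigma_i^2 + mu_i^2 - 1 - log sigma_i^2).

For the hierarchical model each level is regularized against a
standard-normal prior and the per-level divergences are summed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, soft_dtw_batch
from .dtw import SoftDtwConfig
from .models import LatentDistribution

__all__ = ["gaussian_kl", "hierarchical_kl", "total_loss", "kl_graph"]


def _kl_arrays(mu: np.ndarray, logvar: np.ndarray) -> float:
    if not np.all(np.isfinite(logvar)):
        raise ValueError("logvar must be finite")
    var = np.exp(logvar)
    return float(0.5 * np.sum(var + mu ** 2 - 1.0 - logvar))


def gaussian_kl(dist: LatentDistribution) -> float:
    """Closed-form KL(q || N(0, I)) for one diagonal-Gaussian posterior."""
    return _kl_arrays(np.asarray(dist.mu), np.asarray(dist.logvar))


def hierarchical_kl(dists: list[LatentDistribution]) -> float:
    """Sum of per-level KL terms (standard-normal prior at every level)."""
    if not dists:
        raise ValueError("at least one latent distribution is required")
    return float(sum(gaussian_kl(d) for d in dists))


def kl_graph(stats) -> Tensor:
    """In-graph KL for the trainer: mean over batch of the per-element sum."""
    total = None
    for mu, logvar, _level in stats:
        var = logvar.exp()
        per = (var + mu * mu - 1.0 - logvar) * 0.5
        n = per.data.shape[0]
        term = per.sum() * (1.0 / n)
        total = term if total is None else total + term
    return total


def total_loss(x: np.ndarray, x_hat: np.ndarray, dists: list[LatentDistribution],
               kl_weight: float = 1.0, dtw_cfg: SoftDtwConfig | None = None
               ) -> tuple[float, float, float]:
    """(L_total, L_KL, L_R) for already-materialized arrays (logging path)."""
    dtw_cfg = dtw_cfg or SoftDtwConfig()
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    l_r = float(soft_dtw_batch(Tensor(x_hat), x, dtw_cfg).data)
    l_kl = hierarchical_kl(dists) / x.shape[0]
    return kl_weight * l_kl + l_r, l_kl, l_r
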