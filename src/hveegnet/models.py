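"""EEGNet-style variational autoencoders for multi-channel EEG.

Two variants are provided:

* ``vEEGNet-ver3`` — a plain VAE.  The encoder is the EEGNet stack
  (temporal convolution -> batch norm; spatial depthwise convolution ->
  batch norm -> ELU -> average pooling (1,4) -> dropout; separable
  convolution -> batch norm -> ELU -> average pooling (1,8) -> dropout)
  followed by a 1x1 sampling head that doubles the depth; the first half of
  the doubled map is the posterior mean, the second half the log-variance.
  The decoder mirrors the encoder with nearest-neighbour upsampling and
  transposed convolutions.

* ``hvEEGNet`` — the hierarchical variant with three latent spaces tapped at
  the output of each encoder block: z3 after the temporal block, z2 after
  the spatial block (which uses no pooling here), z1 after the separable
  block (pooling (1,10)).  Decoding starts from z1; the sampled z2 is
  temporally filtered (depthwise half-second kernel) and fused with the
  separable-transpose output by a learned pointwise linear combination; the
  sampled z3 is added to the spatial-transpose output before the temporal
  block.

Bias convention (it fixes the trainable-parameter totals): convolutions
adjacent to a batch norm carry no bias; every latent-path convolution
(sampling heads, the z2 injection filter and fusion) carries one.  With the
default 22-channel, 1000-sample configuration this yields 4,992 trainable
parameters for vEEGNet-ver3 and 8,224 for hvEEGNet.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat_channels
from .nn import BatchNorm2d, Context, Conv2d

__all__ = [
    "ArchitectureConfig",
    "LatentDistribution",
    "build_model",
    "reparameterize",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "VEEGNet3",
    "HVEEGNet",
]

VARIANTS = ("veegnet-ver3", "hveegnet")


@dataclass
class ArchitectureConfig:
    """Shapes and kernels of the EEGNet encoder/decoder pair.

    ``z2_filter_kernel`` is the depthwise temporal filter applied to the
    sampled z2 before fusion (hierarchical variant only); the default 125
    taps is half the benchmark sampling rate (250 Hz), odd so that
    same-padding is symmetric.
    """

    n_channels: int = 22
    n_samples: int = 1000
    temporal_kernel: int = 128
    separable_kernel: int = 32
    z2_filter_kernel: int = 125
    f1: int = 8
    depth_multiplier: int = 2
    dropout_p: float = 0.5

    @property
    def f2(self) -> int:
        return self.f1 * self.depth_multiplier

    def validate(self, variant: str) -> None:
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("n_channels and n_samples must be positive")
        for k in (self.temporal_kernel, self.separable_kernel, self.z2_filter_kernel):
            if k < 1:
                raise ValueError("kernel lengths must be >= 1")
        pools = (4, 8) if variant == "veegnet-ver3" else (10,)
        t = self.n_samples
        for p in pools:
            t = t // p
            if t < 1:
                raise ValueError(
                    f"n_samples={self.n_samples} collapses below one sample under the "
                    f"{variant} pooling policy {pools}; use a longer segment")


@dataclass
class LatentDistribution:
    """Diagonal-Gaussian posterior q(z_l | x) at one hierarchy level.

    ``level`` 0 is vEEGNet-ver3's single space; for hvEEGNet level 1 is the
    deepest latent (after the separable block) and level 3 the shallowest
    (after the temporal block).  ``shape`` is the feature-map shape of one
    sample, ``(depth, height, time)``.
    """

    mu: np.ndarray
    logvar: np.ndarray
    level: int
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must share a shape")
        if not np.all(np.isfinite(self.logvar)):
            raise ValueError("logvar must be finite")

    @property
    def n_dim(self) -> int:
        return int(np.prod(self.shape))


def reparameterize(dist: LatentDistribution, seed: int | np.random.Generator = 0,
                   deterministic: bool = False) -> np.ndarray:
    """Draw ``z = mu + exp(logvar/2) * eps`` with standard-normal ``eps``.

    ``deterministic=True`` is the sigma=0 mode: it returns the mean exactly.
    """
    if deterministic:
        return dist.mu.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(dist.mu.shape)
    return dist.mu + np.exp(dist.logvar / 2.0) * eps


class _Base:
    """Common plumbing: parameter registry, eval/train contexts, numpy API."""

    variant: str
    cfg: ArchitectureConfig

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self._layers:
            out.extend(layer.parameters())
        return out

    def batchnorms(self) -> list[BatchNorm2d]:
        return [l for l in self._layers if isinstance(l, BatchNorm2d)]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:  # (N, C, T) -> (N, 1, C, T)
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.cfg.n_channels \
                or x.shape[3] != self.cfg.n_samples:
            raise ValueError(
                f"expected input of shape (N, 1, {self.cfg.n_channels}, "
                f"{self.cfg.n_samples}), got {x.shape}")
        return x

    # -- public numpy-level API -------------------------------------------
    def encode(self, x: np.ndarray) -> list[LatentDistribution]:
        """Posterior distributions for a batch; deterministic (eval mode)."""
        x = self._check_input(x)
        ctx = Context(training=False)
        stats = self.encode_graph(Tensor(x), ctx)
        return [LatentDistribution(mu=m.data, logvar=lv.data, level=lev,
                                   shape=m.data.shape[1:])
                for (m, lv, lev) in stats]

    def forward(self, x: np.ndarray, seed: int | np.random.Generator = 0,
                sample: bool = True) -> np.ndarray:
        """Encode, (re)sample and decode; ``sample=False`` decodes the means."""
        x = self._check_input(x)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ctx = Context(training=False, rng=rng)
        xh, _ = self.forward_graph(Tensor(x), ctx, sample=sample)
        return xh.data

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Posterior-mean (zero-noise) reconstruction — the scoring convention."""
        return self.forward(x, sample=False)


class VEEGNet3(_Base):
    """Single-latent VAE (vEEGNet-ver3)."""

    variant = "veegnet-ver3"
    pool1, pool2 = 4, 8

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        cfg.validate(self.variant)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.seed = seed
        C, f1, f2 = cfg.n_channels, cfg.f1, cfg.f2
        # encoder
        self.conv_temporal = Conv2d(1, f1, (1, cfg.temporal_kernel), bias=False, rng=rng)
        self.bn_t = BatchNorm2d(f1)
        self.conv_spatial = Conv2d(f1, f2, (C, 1), groups=f1, bias=False,
                                   padding="valid", rng=rng)
        self.bn_s = BatchNorm2d(f2)
        self.conv_sep_dw = Conv2d(f2, f2, (1, cfg.separable_kernel), groups=f2,
                                  bias=False, rng=rng)
        self.conv_sep_pw = Conv2d(f2, f2, (1, 1), bias=False, rng=rng)
        self.bn_sep = BatchNorm2d(f2)
        self.head_z0 = Conv2d(f2, 2 * f2, (1, 1), bias=True, rng=rng)
        # decoder (mirror; transpose convs are stride-1, so plain convs with
        # the transpose padding geometry)
        self.bn_d3 = BatchNorm2d(f2)
        self.deconv_sep_pw = Conv2d(f2, f2, (1, 1), bias=False, rng=rng)
        self.deconv_sep_dw = Conv2d(f2, f2, (1, cfg.separable_kernel), groups=f2,
                                    bias=False, rng=rng)
        self.bn_d2 = BatchNorm2d(f2)
        self.deconv_spatial = Conv2d(f2, f1, (C, 1), groups=f1, bias=False,
                                     padding="valid", rng=rng)
        self.deconv_spatial.pad_h = (C - 1, C - 1)  # transpose geometry: 1 -> C rows
        self.bn_d1 = BatchNorm2d(f1)
        self.deconv_temporal = Conv2d(f1, 1, (1, cfg.temporal_kernel), bias=False, rng=rng)
        self._layers = [
            self.conv_temporal, self.bn_t, self.conv_spatial, self.bn_s,
            self.conv_sep_dw, self.conv_sep_pw, self.bn_sep, self.head_z0,
            self.bn_d3, self.deconv_sep_pw, self.deconv_sep_dw, self.bn_d2,
            self.deconv_spatial, self.bn_d1, self.deconv_temporal,
        ]
        t = cfg.n_samples
        self.len_t = t                      # after temporal/spatial convs
        self.len_p1 = t // self.pool1       # after spatial-block pooling
        self.len_p2 = self.len_p1 // self.pool2  # after separable-block pooling

    # graph-level pieces (used by both the numpy API and the trainer) -------
    def encode_graph(self, x: Tensor, ctx: Context):
        h = self.bn_t(self.conv_temporal(x, ctx), ctx)
        h = self.bn_s(self.conv_spatial(h, ctx), ctx).elu()
        h = h.avg_pool_w(self.pool1).dropout(self.cfg.dropout_p, ctx.rng, ctx.training)
        h = self.conv_sep_pw(self.conv_sep_dw(h, ctx), ctx)
        h = self.bn_sep(h, ctx).elu()
        h = h.avg_pool_w(self.pool2).dropout(self.cfg.dropout_p, ctx.rng, ctx.training)
        doubled = self.head_z0(h, ctx)
        f2 = self.cfg.f2
        return [(doubled.slice_channels(0, f2), doubled.slice_channels(f2, 2 * f2), 0)]

    def decode_graph(self, z0: Tensor, ctx: Context) -> Tensor:
        p = self.cfg.dropout_p
        h = z0.dropout(p, ctx.rng, ctx.training)
        h = h.upsample_w(self.pool2, self.len_p1).elu()
        h = self.bn_d3(h, ctx)
        h = self.deconv_sep_dw(self.deconv_sep_pw(h, ctx), ctx)
        h = h.dropout(p, ctx.rng, ctx.training)
        h = h.upsample_w(self.pool1, self.len_t).elu()
        h = self.bn_d2(h, ctx)
        h = self.deconv_spatial(h, ctx)
        h = self.bn_d1(h, ctx)
        return self.deconv_temporal(h, ctx)

    def forward_graph(self, x: Tensor, ctx: Context, sample: bool = True):
        stats = self.encode_graph(x, ctx)
        mu, logvar, _ = stats[0]
        if sample:
            eps = ctx.rng.standard_normal(mu.data.shape)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        return self.decode_graph(z, ctx), stats

    def decode(self, z0: np.ndarray) -> np.ndarray:
        """Numpy-level decode of a (N, f2, 1, T') latent sample."""
        ctx = Context(training=False)
        return self.decode_graph(Tensor(np.asarray(z0, dtype=np.float64)), ctx).data


class HVEEGNet(_Base):
    """Hierarchical VAE with three latent spaces (hvEEGNet)."""

    variant = "hveegnet"
    pool_sep = 10

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        cfg.validate(self.variant)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.seed = seed
        C, f1, f2 = cfg.n_channels, cfg.f1, cfg.f2
        self.conv_temporal = Conv2d(1, f1, (1, cfg.temporal_kernel), bias=False, rng=rng)
        self.bn_t = BatchNorm2d(f1)
        self.conv_spatial = Conv2d(f1, f2, (C, 1), groups=f1, bias=False,
                                   padding="valid", rng=rng)
        self.bn_s = BatchNorm2d(f2)
        self.conv_sep_dw = Conv2d(f2, f2, (1, cfg.separable_kernel), groups=f2,
                                  bias=False, rng=rng)
        self.conv_sep_pw = Conv2d(f2, f2, (1, 1), bias=False, rng=rng)
        self.bn_sep = BatchNorm2d(f2)
        # posterior sampling heads (1x1, depth-doubling, biased)
        self.head_z3 = Conv2d(f1, 2 * f1, (1, 1), bias=True, rng=rng)
        self.head_z2 = Conv2d(f2, 2 * f2, (1, 1), bias=True, rng=rng)
        self.head_z1 = Conv2d(f2, 2 * f2, (1, 1), bias=True, rng=rng)
        # decoder
        self.bn_d3 = BatchNorm2d(f2)
        self.deconv_sep_pw = Conv2d(f2, f2, (1, 1), bias=False, rng=rng)
        self.deconv_sep_dw = Conv2d(f2, f2, (1, cfg.separable_kernel), groups=f2,
                                    bias=False, rng=rng)
        # z2 injection: depthwise half-second temporal filter on the sample,
        # then a learned pointwise linear combination with the decoder features
        self.z2_filter = Conv2d(f2, f2, (1, cfg.z2_filter_kernel), groups=f2,
                                bias=True, rng=rng)
        self.z2_fusion = Conv2d(2 * f2, f2, (1, 1), bias=True, rng=rng)
        self.bn_d2 = BatchNorm2d(f2)
        self.deconv_spatial = Conv2d(f2, f1, (C, 1), groups=f1, bias=False,
                                     padding="valid", rng=rng)
        self.deconv_spatial.pad_h = (C - 1, C - 1)
        self.bn_d1 = BatchNorm2d(f1)
        self.deconv_temporal = Conv2d(f1, 1, (1, cfg.temporal_kernel), bias=False, rng=rng)
        self._layers = [
            self.conv_temporal, self.bn_t, self.conv_spatial, self.bn_s,
            self.conv_sep_dw, self.conv_sep_pw, self.bn_sep,
            self.head_z3, self.head_z2, self.head_z1,
            self.bn_d3, self.deconv_sep_pw, self.deconv_sep_dw,
            self.z2_filter, self.z2_fusion,
            self.bn_d2, self.deconv_spatial, self.bn_d1, self.deconv_temporal,
        ]
        self.len_t = cfg.n_samples
        self.len_sep = cfg.n_samples // self.pool_sep

    def encode_graph(self, x: Tensor, ctx: Context):
        """Returns [(mu, logvar, level)] ordered deepest first: z1, z2, z3."""
        f1, f2 = self.cfg.f1, self.cfg.f2
        h_t = self.bn_t(self.conv_temporal(x, ctx), ctx)
        h_s = self.bn_s(self.conv_spatial(h_t, ctx), ctx).elu()
        h_s = h_s.dropout(self.cfg.dropout_p, ctx.rng, ctx.training)  # no pooling
        h = self.conv_sep_pw(self.conv_sep_dw(h_s, ctx), ctx)
        h = self.bn_sep(h, ctx).elu()
        h = h.avg_pool_w(self.pool_sep).dropout(self.cfg.dropout_p, ctx.rng, ctx.training)
        d1 = self.head_z1(h, ctx)
        d2 = self.head_z2(h_s, ctx)
        d3 = self.head_z3(h_t, ctx)
        return [
            (d1.slice_channels(0, f2), d1.slice_channels(f2, 2 * f2), 1),
            (d2.slice_channels(0, f2), d2.slice_channels(f2, 2 * f2), 2),
            (d3.slice_channels(0, f1), d3.slice_channels(f1, 2 * f1), 3),
        ]

    def decode_graph(self, z1: Tensor, z2: Tensor | None, z3: Tensor | None,
                     ctx: Context) -> Tensor:
        p = self.cfg.dropout_p
        h = z1.dropout(p, ctx.rng, ctx.training)
        h = h.upsample_w(self.pool_sep, self.len_t).elu()
        h = self.bn_d3(h, ctx)
        h = self.deconv_sep_dw(self.deconv_sep_pw(h, ctx), ctx)
        if z2 is None:
            z2 = Tensor(np.zeros_like(h.data))
        filt = self.z2_filter(z2, ctx)
        h = self.z2_fusion(concat_channels(h, filt), ctx)
        h = h.dropout(p, ctx.rng, ctx.training).elu()
        h = self.bn_d2(h, ctx)
        h = self.deconv_spatial(h, ctx)
        if z3 is not None:
            h = h + z3
        h = self.bn_d1(h, ctx)
        return self.deconv_temporal(h, ctx)

    def forward_graph(self, x: Tensor, ctx: Context, sample: bool = True):
        stats = self.encode_graph(x, ctx)

        def draw(mu, logvar):
            if not sample:
                return mu
            eps = ctx.rng.standard_normal(mu.data.shape)
            return mu + (logvar * 0.5).exp() * Tensor(eps)

        z1, z2, z3 = (draw(m, lv) for (m, lv, _) in stats)
        return self.decode_graph(z1, z2, z3, ctx), stats

    def decode(self, z1: np.ndarray, z2: np.ndarray | None = None,
               z3: np.ndarray | None = None) -> np.ndarray:
        """Partial-hierarchy decode: omitted levels are decoded as zero.

        ``decode(z1)`` reproduces the deepest-latent-only reconstruction,
        ``decode(z1, z2)`` adds the spatial level, ``decode(z1, z2, z3)``
        the full hierarchy.
        """
        ctx = Context(training=False)
        t = lambda a: None if a is None else Tensor(np.asarray(a, dtype=np.float64))
        return self.decode_graph(t(z1), t(z2), t(z3), ctx).data


def build_model(cfg: ArchitectureConfig | None = None, variant: str = "hveegnet",
                seed: int = 0):
    """Instantiate one of the two autoencoder variants."""
    cfg = cfg or ArchitectureConfig()
    variant = variant.lower()
    if variant in ("veegnet-ver3", "veegnet3", "veegnet"):
        return VEEGNet3(cfg, seed=seed)
    if variant in ("hveegnet", "hv"):
        return HVEEGNet(cfg, seed=seed)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def count_parameters(model) -> int:
    """Number of trainable scalars (conv weights/biases, BN affine terms)."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def save_checkpoint(model, path) -> None:
    """Single-file checkpoint: weights + running stats + a JSON header."""
    header = json.dumps({"variant": model.variant, "seed": model.seed,
                         "config": asdict(model.cfg)})
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, header=np.array(header), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        model = build_model(ArchitectureConfig(**header["config"]),
                            header["variant"], seed=header["seed"])
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        for i, bn in enumerate(model.batchnorms()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    return model
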