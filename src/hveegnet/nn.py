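"""Neural-network layers and the Adam optimizer used by the EEG autoencoders.

Conventions follow the EEGNet family: convolutions that feed a batch
normalization carry no bias (the BN shift absorbs it); latent-path
convolutions (sampling heads, injection filters, fusion) do carry biases.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Context", "Conv2d", "BatchNorm2d", "Adam", "glorot_uniform"]


class Context:
    """Per-forward state: train/eval mode and the noise generator."""

    def __init__(self, training: bool = False, rng: np.random.Generator | None = None):
        self.training = training
        self.rng = rng if rng is not None else np.random.default_rng(0)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2d:
    """Stride-1 grouped 2-D convolution with explicit per-axis padding.

    ``padding="same_w"`` pads the time axis so the output keeps its length
    (left ``(k-1)//2``, right ``k//2``); ``"valid"`` applies no padding.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 groups: int = 1, bias: bool = True, padding: str = "same_w",
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        kh, kw = kernel
        fan_in = (in_ch // groups) * kh * kw
        fan_out = (out_ch // groups) * kh * kw
        self.weight = Parameter(glorot_uniform(rng, (out_ch, in_ch // groups, kh, kw),
                                               fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.groups = groups
        self.kernel = kernel
        if padding == "same_w":
            self.pad_h = (0, 0)
            self.pad_w = ((kw - 1) // 2, kw // 2)
        elif padding == "valid":
            self.pad_h = (0, 0)
            self.pad_w = (0, 0)
        else:
            raise ValueError(f"unknown padding {padding!r}")

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return x.conv2d(self.weight, self.bias, groups=self.groups,
                        pad_h=self.pad_h, pad_w=self.pad_w)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d:
    """Per-channel batch normalization with affine parameters and running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        if ctx.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adaptive-moment optimizer with an exponential per-epoch LR schedule."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
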