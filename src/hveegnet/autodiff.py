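"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the EEG autoencoders need are implemented: broadcasted
arithmetic, reductions, ELU, 2-D convolution (stride 1, grouped, asymmetric
padding), average pooling and nearest-neighbour upsampling along the time
axis, channel concatenation/slicing, dropout, and a custom soft-DTW node
whose backward pass is the expected-alignment recursion from dtw.py.

Gradients accumulate into ``Tensor.grad``; ``backward()`` runs a topological
sort from the loss node.  Everything is float64 and single-threaded, which
keeps runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .dtw import SoftDtwConfig, _soft_backward, _soft_forward

__all__ = ["Tensor", "Parameter", "concat_channels", "soft_dtw_batch"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            out._backward = lambda g: (self._accum(g * other.data),
                                       other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def pow(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).copy())
                    return
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, shape).copy())

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        y = np.where(x > 0, x, neg)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            dydx = np.where(x > 0, 1.0, neg + alpha)
            out._backward = lambda g: self._accum(g * dydx)
        return out

    # -- structural ops ----------------------------------------------------
    def slice_channels(self, start: int, stop: int):
        out = Tensor(self.data[:, start:stop], parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accum(full)
            out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)

    # -- time-axis pooling / upsampling (layout N, C, H, W; W = time) ------
    def avg_pool_w(self, factor: int):
        n, c, h, w = self.data.shape
        wout = w // factor
        x = self.data[..., :wout * factor].reshape(n, c, h, wout, factor)
        out = Tensor(x.mean(axis=-1), parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                full[..., :wout * factor] = np.repeat(g / factor, factor, axis=-1)
                self._accum(full)
            out._backward = bw
        return out

    def upsample_w(self, factor: int, target_len: int):
        """Nearest-neighbour repeat by ``factor`` then crop/edge-pad to ``target_len``."""
        n, c, h, w = self.data.shape
        up = np.repeat(self.data, factor, axis=-1)
        wl = up.shape[-1]
        if wl >= target_len:
            y = up[..., :target_len]
        else:
            pad = np.repeat(up[..., -1:], target_len - wl, axis=-1)
            y = np.concatenate([up, pad], axis=-1)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def bw(g):
                gg = np.zeros((n, c, h, wl))
                if wl >= target_len:
                    gg[..., :target_len] = g
                else:
                    gg[...] = g[..., :wl]
                    gg[..., -1] += g[..., wl:].sum(axis=-1)
                self._accum(gg.reshape(n, c, h, w, factor).sum(axis=-1))
            out._backward = bw
        return out

    # -- convolution (stride 1, grouped, explicit padding) ------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None", groups: int = 1,
               pad_h: tuple[int, int] = (0, 0), pad_w: tuple[int, int] = (0, 0)):
        x = self.data
        wdat = weight.data
        n, cin, h, w = x.shape
        cout, cin_g, kh, kw = wdat.shape
        assert cin == cin_g * groups, "channel/group mismatch"
        xp = np.pad(x, ((0, 0), (0, 0), pad_h, pad_w))
        hp, wp = xp.shape[2], xp.shape[3]
        ho, wo = hp - kh + 1, wp - kw + 1
        s = xp.strides
        cols = as_strided(xp, (n, cin, kh, kw, ho, wo),
                          (s[0], s[1], s[2], s[3], s[2], s[3]))
        cols_g = cols.reshape(n, groups, cin // groups, kh, kw, ho, wo)
        w_g = wdat.reshape(groups, cout // groups, cin // groups, kh, kw)
        y = np.einsum("ngikluv,goikl->ngouv", cols_g, w_g, optimize=True)
        y = y.reshape(n, cout, ho, wo)
        if bias is not None:
            y = y + bias.data.reshape(1, cout, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(y, parents=parents)
        if out.requires_grad:
            def bw(g):
                g_g = g.reshape(n, groups, cout // groups, ho, wo)
                gw = np.einsum("ngikluv,ngouv->goikl", cols_g, g_g, optimize=True)
                weight._accum(gw.reshape(cout, cin // groups, kh, kw))
                if bias is not None:
                    bias._accum(g.sum(axis=(0, 2, 3)))
                if not self.requires_grad:
                    return
                gxp = np.zeros_like(xp).reshape(n, groups, cin // groups, hp, wp)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, :, :, di:di + ho, dj:dj + wo] += np.einsum(
                            "ngouv,goi->ngiuv", g_g, w_g[:, :, :, di, dj],
                            optimize=True)
                gxp = gxp.reshape(n, cin, hp, wp)
                self._accum(gxp[:, :,
                                pad_h[0]:hp - pad_h[1] or None,
                                pad_w[0]:wp - pad_w[1] or None])
            out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))
    if out.requires_grad:
        ca = a.data.shape[1]

        def bw(g):
            a._accum(g[:, :ca])
            b._accum(g[:, ca:])

        out._backward = bw
    return out


def soft_dtw_batch(x_hat: Tensor, x: np.ndarray, cfg: SoftDtwConfig) -> Tensor:
    """Channel-summed, batch-meaned soft-DTW between reconstruction and target.

    ``x_hat`` is a ``(N, 1, C, T)`` tensor in the graph, ``x`` the constant
    target of the same shape.  Returns a scalar tensor; the backward pass uses
    the expected-alignment matrix of the soft-min relaxation.
    """
    xh = x_hat.data
    n, _, c, t = xh.shape
    band = cfg.bandwidth if cfg.bandwidth is not None else 0
    total = 0.0
    grads = np.zeros_like(xh)
    for i in range(n):
        for ch in range(c):
            a = xh[i, 0, ch]
            b = x[i, 0, ch]
            diff = a[:, None] - b[None, :]
            cost = np.abs(diff)
            R = _soft_forward(cost, cfg.gamma, band)
            E = _soft_backward(cost, R, cfg.gamma, band)
            total += R[-1, -1]
            grads[i, 0, ch] = (E * np.sign(diff)).sum(axis=1)
    out = Tensor(total / n, parents=(x_hat,))
    if out.requires_grad:
        out._backward = lambda g: x_hat._accum(g * grads / n)
    return out
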