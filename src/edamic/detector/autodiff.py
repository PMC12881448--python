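"""A minimal reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the detector architectures need: im2col 3x3
convolution, 2x2 max-pooling, nearest-neighbour upsampling, channel
concatenation/slicing, pointwise nonlinearities, and reductions. Array
layout is (N, C, H, W) throughout.

This exists because the execution environment provides no deep-learning
framework; the networks here are small enough (depth-2 U-Nets, 16 initial
filters) that numpy matmul convolutions are fast enough on one CPU.
"""

from __future__ import annotations

import numpy as np

#: Array dtype for the whole engine. float32 keeps the conv workloads within
#: one CPU's memory bandwidth; switch to float64 for high-precision checks.
DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- convenience arithmetic (only what the models/losses use) --

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(-_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1 - t * t))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    clipped = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)
    out = Tensor(clipped, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def abs_(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g * np.sign(x.data))
    return out


def pow_const(x: Tensor, p: float) -> Tensor:
    """x ** p for non-negative x (as used on |t - p| modulations)."""
    val = np.power(x.data, p)
    out = Tensor(val, parents=(x,))

    def bwd(g):
        base = np.where(x.data == 0, 0.0, np.power(np.maximum(x.data, 1e-300), p - 1))
        x._accumulate(g * p * base)

    out._backward = bwd
    return out


def mean(x: Tensor) -> Tensor:
    out = Tensor(np.mean(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(np.full(x.shape, g / x.data.size))
    return out


def concat_channels(tensors) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=1), parents=tuple(tensors))
    sizes = [d.shape[1] for d in datas]

    def bwd(g):
        c0 = 0
        for t, s in zip(tensors, sizes):
            t._accumulate(g[:, c0:c0 + s])
            c0 += s

    out._backward = bwd
    return out


def narrow_channels(x: Tensor, c0: int, c1: int) -> Tensor:
    out = Tensor(x.data[:, c0:c1], parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, c0:c1] = g
        x._accumulate(full)

    out._backward = bwd
    return out


# -- convolution --

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    xp[:, :, pad:pad + h, pad:pad + w] = x
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return np.ascontiguousarray(windows).reshape(n, c * k * k, h * w)


def _col2im(dcol: np.ndarray, xshape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcol[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 2D convolution; weight is (F, C, k, k), k odd."""
    f, c, k, _ = weight.shape
    pad = k // 2
    n, _, h, w = x.shape
    col = _im2col(x.data, k, pad)                       # (n, c*k*k, h*w)
    w2 = weight.data.reshape(f, c * k * k)
    y = (w2 @ col).reshape(n, f, h, w) + bias.data.reshape(1, f, 1, 1)
    out = Tensor(y, parents=(x, weight, bias))

    def bwd(g):
        g2 = g.reshape(n, f, h * w)
        if weight.requires_grad:
            dw = np.matmul(g2, col.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.shape))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcol = np.matmul(w2.T, g2)
            x._accumulate(_col2im(dcol, x.data.shape, k, pad))

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    hb, wb = h // 2, w // 2
    # windows laid out (n, c, hb, wb, 4) so argmax tie-breaking is local
    win = (x.data.reshape(n, c, hb, 2, wb, 2)
           .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hb, wb, 4))
    first = np.argmax(win, axis=-1)
    y = np.take_along_axis(win, first[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def bwd(g):
        gwin = np.zeros((n, c, hb, wb, 4), dtype=g.dtype)
        np.put_along_axis(gwin, first[..., None], g[..., None], axis=-1)
        x._accumulate(gwin.reshape(n, c, hb, wb, 2, 2)
                      .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
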