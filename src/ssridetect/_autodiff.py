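"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the ConvLSTM classifier needs — broadcast
add/multiply, matmul, stride-1 'same' 2-d convolution, 2x2 max-pooling,
sigmoid/tanh, reshape, concatenation, channel narrowing, and a fused
class-weighted binary cross-entropy on logits — each with an analytically
derived backward rule.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the computation graph: value, accumulated gradient, parents."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(float)
        self.data = data
        self.grad = None
        self.parents = parents  # tuple of (Tensor, grad_fn)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed_grad=None):
        """Accumulate gradients into every reachable requires_grad tensor."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative post-order DFS: the unrolled graph is deep
            node, expanded = stack.pop()
            if not node.requires_grad:
                continue
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if seed_grad is None else np.asarray(seed_grad)
        for t in reversed(topo):
            if t.grad is None:
                continue
            for parent, grad_fn in t.parents:
                if not parent.requires_grad:
                    continue
                contribution = grad_fn(t.grad)
                if parent.grad is None:
                    parent.grad = contribution.copy()
                else:
                    parent.grad += contribution

    def zero_grad(self):
        self.grad = None


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data,
        parents=(
            (a, lambda g: g @ b.data.T),
            (b, lambda g: a.data.T @ g),
        ),
    )


def sigmoid(x: Tensor) -> Tensor:
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    out[~pos] = e / (1.0 + e)
    return Tensor(out, parents=((x, lambda g: g * out * (1.0 - out)),))


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)
    return Tensor(out, parents=((x, lambda g: g * (1.0 - out**2)),))


def reshape(x: Tensor, shape: tuple) -> Tensor:
    old = x.data.shape
    return Tensor(x.data.reshape(shape), parents=((x, lambda g: g.reshape(old)),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * tensors[i].data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        return lambda g: g[tuple(sl)]

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple((t, make_fn(i)) for i, t in enumerate(tensors)),
    )


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along ``axis`` (used to split stacked gate channels)."""
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def grad_fn(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        return full

    return Tensor(x.data[sl], parents=((x, grad_fn),))


def _conv2d_raw(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 'same' zero-padded correlation.

    x: (B, H, W, Cin), w: (kh, kw, Cin, Cout) with odd kh, kw.
    Returns (output (B, H, W, Cout), the zero-padded input).  The im2col
    buffer is transient: only the (much smaller) padded input is kept for
    the backward pass, which recomputes window slices shift by shift.
    """
    kh, kw, cin, cout = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # (B, H, W, Cin, kh, kw) -> (B, H, W, kh, kw, Cin)
    windows = sliding_window_view(xp, (kh, kw), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)
    b, h, wd = x.shape[0], x.shape[1], x.shape[2]
    cols = np.ascontiguousarray(windows).reshape(b * h * wd, kh * kw * cin)
    out = (cols @ w.reshape(kh * kw * cin, cout)).reshape(b, h, wd, cout)
    return out, xp


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' 2-d convolution with bias.

    Both gradients use the shift-and-add adjoint (9 small GEMMs over strided
    slices of the padded arrays) rather than materialising im2col windows,
    which keeps the autodiff graph's memory footprint small.
    """
    out, xp = _conv2d_raw(x.data, w.data)
    kh, kw, cin, cout = w.data.shape
    ph, pw = kh // 2, kw // 2

    def grad_x(g):
        bsz, h, wd = g.shape[:3]
        dxp = np.zeros((bsz, h + 2 * ph, wd + 2 * pw, cin), dtype=g.dtype)
        g2 = g.reshape(-1, cout)
        for dy in range(kh):
            for dx in range(kw):
                dxp[:, dy : dy + h, dx : dx + wd, :] += (
                    g2 @ w.data[dy, dx].T
                ).reshape(bsz, h, wd, cin)
        return dxp[:, ph : ph + h, pw : pw + wd, :]

    def grad_w(g):
        bsz, h, wd = g.shape[:3]
        g2 = g.reshape(-1, cout)
        gw = np.empty((kh, kw, cin, cout), dtype=g.dtype)
        for dy in range(kh):
            for dx in range(kw):
                sl = xp[:, dy : dy + h, dx : dx + wd, :].reshape(-1, cin)
                gw[dy, dx] = sl.T @ g2
        return gw

    return Tensor(
        out + b.data,
        parents=(
            (x, grad_x),
            (w, grad_w),
            (b, lambda g: g.sum(axis=(0, 1, 2))),
        ),
    )


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, on (B, H, W, C); H and W must be even."""
    b, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {(h, w)}")
    blocks = x.data.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    blocks = blocks.reshape(b, h // 2, w // 2, 4, c)
    arg = blocks.argmax(axis=3)
    out = np.take_along_axis(blocks, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def grad_fn(g):
        gb = np.zeros((b, h // 2, w // 2, 4, c), dtype=g.dtype)
        np.put_along_axis(gb, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gb = gb.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return gb.reshape(b, h, w, c)

    return Tensor(out, parents=((x, grad_fn),))


def weighted_bce_with_logits(z: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    """Mean over the batch of w_i * BCE(sigmoid(z_i), y_i), numerically stable."""
    zd = z.data.reshape(-1)
    y = np.asarray(y, dtype=zd.dtype).reshape(-1)
    w = np.asarray(w, dtype=zd.dtype).reshape(-1)
    per = np.maximum(zd, 0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    loss = float((w * per).mean())
    n = zd.size

    def grad_fn(g):
        p = np.where(zd >= 0, 1.0 / (1.0 + np.exp(-zd)), np.exp(zd) / (1.0 + np.exp(zd)))
        return (g * w * (p - y) / n).reshape(z.data.shape)

    return Tensor(loss, parents=((z, grad_fn),))


class Adam:
    """Adaptive-moment estimation over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
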