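"""Reverse-mode automatic differentiation on NumPy arrays.

A small tensor engine tailored to the convolutional fusion network in this
package: it implements exactly the primitives the model needs (dense and
depthwise convolution, batch normalisation, SiLU/ReLU/sigmoid, pooling,
concatenation, cross-entropy and L1 losses) with hand-derived backward
passes.  Every primitive is covered by finite-difference gradient checks in
the test suite.

Tensors wrap ``numpy`` arrays; calling :meth:`Tensor.backward` on a scalar
output walks the recorded graph in reverse topological order and accumulates
gradients into every reachable tensor with ``requires_grad`` set.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "conv2d",
    "dwconv2d",
    "batchnorm2d",
    "relu",
    "sigmoid",
    "silu",
    "spatial_mean",
    "reshape",
    "concat",
    "softmax",
    "softmax_cross_entropy",
    "l1_loss",
]


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Operator sugar used sparingly by the layers.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad and t._backward is None and not t._parents:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _needs_graph(*ts):
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward):
    track = _needs_graph(*parents)
    return Tensor(data, _parents=tuple(parents) if track else (),
                  _backward=backward if track else None)


# ---------------------------------------------------------------------------
# elementwise / linear algebra


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a, s: float):
    a = _as_tensor(a)
    s = float(s)

    def backward(g):
        _accumulate(a, g * s)

    return _make(a.data * s, (a,), backward)


def matmul(a, b):
    """2-d matrix product ``(N, d) @ (d, m)``."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution


def _pad_input(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x, w, stride: int = 1, padding: int = 0):
    """Dense 2-d convolution, NCHW layout, bias-free.

    ``x``: (N, C_in, H, W); ``w``: (C_out, C_in, K, K).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c_in, _, _ = x.data.shape
    c_out, c_in_w, kh, kw = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_in_w}")
    s, p = int(stride), int(padding)

    if kh == 1 and kw == 1 and s == 1 and p == 0:
        w2 = w.data.reshape(c_out, c_in)
        out_data = np.tensordot(w2, x.data, axes=([1], [1])).transpose(1, 0, 2, 3)
        out_data = np.ascontiguousarray(out_data)

        def backward(g):
            dw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
            _accumulate(w, dw.reshape(w.data.shape))
            dx = np.tensordot(w2.T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
            _accumulate(x, np.ascontiguousarray(dx))

        return _make(out_data, (x, w), backward)

    xp = _pad_input(x.data, p)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # win: (N, C_in, H_out, W_out, K, K)
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    h_out, w_out = out_data.shape[2], out_data.shape[3]

    def backward(g):
        dw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
        _accumulate(w, dw)
        dxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                contrib = np.tensordot(g, w.data[:, :, ki, kj], axes=([1], [0]))
                dxp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s] += (
                    contrib.transpose(0, 3, 1, 2)
                )
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        _accumulate(x, dxp)

    return _make(out_data, (x, w), backward)


def dwconv2d(x, w, stride: int = 1, padding: int = 0):
    """Depthwise 2-d convolution: one spatial filter per channel.

    ``x``: (N, C, H, W); ``w``: (C, K, K).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    c = x.data.shape[1]
    if w.data.shape[0] != c:
        raise ValueError(f"dwconv2d channel mismatch: input {c}, weight {w.data.shape[0]}")
    kh, kw = w.data.shape[1], w.data.shape[2]
    s, p = int(stride), int(padding)

    xp = _pad_input(x.data, p)
    hp, wp = xp.shape[2], xp.shape[3]
    h_out = (hp - kh) // s + 1
    w_out = (wp - kw) // s + 1

    def _slice(ki, kj):
        return xp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s]

    # accumulate over kernel offsets: contiguous slice ops beat an einsum
    # over the 6-d sliding-window view, which would materialise copies
    out_data = np.zeros((xp.shape[0], c, h_out, w_out), dtype=xp.dtype)
    for ki in range(kh):
        for kj in range(kw):
            out_data += _slice(ki, kj) * w.data[None, :, ki, kj, None, None]

    def backward(g):
        dw = np.empty_like(w.data)
        for ki in range(kh):
            for kj in range(kw):
                dw[:, ki, kj] = np.einsum("nchw,nchw->c", g, _slice(ki, kj))
        _accumulate(w, dw)
        dxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s] += (
                    g * w.data[None, :, ki, kj, None, None]
                )
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        _accumulate(x, dxp)

    return _make(out_data, (x, w), backward)


# ---------------------------------------------------------------------------
# normalisation


def batchnorm2d(x, gamma, beta, running_mean, running_var, *, training: bool,
                momentum: float = 0.1, eps: float = 1e-3):
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain NumPy arrays updated in place
    during training (they are state, not differentiable parameters).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    shape = (1, c, 1, 1)

    if training:
        m = x.data.mean(axis=axes)
        diff = x.data - m.reshape(shape)
        v = np.einsum("nchw,nchw->c", diff, diff) / (x.data.size // c)
        n_red = x.data.size // c
        running_mean *= (1.0 - momentum)
        running_mean += momentum * m
        # unbiased running variance, matching the usual convention
        unbias = n_red / max(n_red - 1, 1)
        running_var *= (1.0 - momentum)
        running_var += momentum * v * unbias
    else:
        m = running_mean
        v = running_var
        n_red = x.data.size // c

    istd = 1.0 / np.sqrt(v + eps)
    if training:
        xhat = diff * istd.reshape(shape)
    else:
        xhat = (x.data - m.reshape(shape)) * istd.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    if training:
        def backward(g):
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            _accumulate(gamma, dgamma)
            _accumulate(beta, dbeta)
            gi = gamma.data * istd
            dx = (gi / n_red).reshape(shape) * (
                n_red * g
                - dbeta.reshape(shape)
                - xhat * dgamma.reshape(shape)
            )
            _accumulate(x, dx)
    else:
        def backward(g):
            _accumulate(gamma, (g * xhat).sum(axis=axes))
            _accumulate(beta, g.sum(axis=axes))
            _accumulate(x, g * (gamma.data * istd).reshape(shape))

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# activations


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accumulate(x, g * mask)

    return _make(out_data, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # overflow-free formulation via tanh
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def sigmoid(x):
    x = _as_tensor(x)
    s = _sigmoid(x.data)

    def backward(g):
        _accumulate(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def silu(x):
    """SiLU activation: x * sigmoid(x)."""
    x = _as_tensor(x)
    s = _sigmoid(x.data)
    out_data = x.data * s

    def backward(g):
        _accumulate(x, g * (s + x.data * s * (1.0 - s)))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# shape ops


def spatial_mean(x):
    """Global average pooling: (N, C, H, W) -> (N, C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        _accumulate(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    return _make(out_data, (x,), backward)


def reshape(x, shape):
    x = _as_tensor(x)
    orig = x.data.shape

    def backward(g):
        _accumulate(x, g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), backward)


def concat(tensors, axis: int = 1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# losses


def softmax(logits) -> np.ndarray:
    """Softmax of a (N, K) array, computed stably.  Returns plain NumPy."""
    z = np.asarray(logits.data if isinstance(logits, Tensor) else logits)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy (nats) of (N, K) logits against integer labels.

    Computed with the log-sum-exp trick; the materialised softmax is never
    formed in the forward pass.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    n, k = logits.data.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    picked = z[np.arange(n), labels]
    out_data = np.asarray((lse - picked).mean(), dtype=logits.data.dtype)

    def backward(g):
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        _accumulate(logits, (g / n) * p)

    return _make(out_data, (logits,), backward)


def l1_loss(pred, target):
    """Mean absolute error between ``pred`` and a constant target array."""
    pred = _as_tensor(pred)
    target = np.asarray(target).reshape(pred.data.shape)
    diff = pred.data - target
    out_data = np.asarray(np.abs(diff).mean(), dtype=pred.data.dtype)

    def backward(g):
        _accumulate(pred, (g / diff.size) * np.sign(diff))

    return _make(out_data, (pred,), backward)
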