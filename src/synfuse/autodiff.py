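"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The trainable network here (graph convolutions, multi-head attention,
layer norm, MLP heads) needs end-to-end gradients.  This module provides a
small tape-based autodiff core: a :class:`Tensor` wrapping an ndarray, a
closed set of differentiable operations (the only ones the model uses), and
an Adam optimizer.  Gradient correctness is pinned by central-difference
checks in the test suite.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
reduced back to the operand shape.  ``matmul`` supports stacked (batched)
operands, so whole minibatches of padded molecular graphs or token matrices
flow through single BLAS calls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "concat",
    "gather",
    "sum_along",
    "transpose_last",
    "softmax_last",
    "log_softmax_last",
    "layer_norm_last",
    "dropout",
    "Adam",
    "backward",
]


class Tensor:
    """An ndarray plus the tape hooks needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # Small operator sugar; constants are wrapped as non-grad tensors.
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _make(data, parents, backward_fn, requires_grad) -> Tensor:
    out = Tensor(data, requires_grad=requires_grad)
    if requires_grad:
        out._parents = parents
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    # Freshly allocated gradients are adopted without a copy.  This is safe
    # under the reverse-topological execution order used by backward():
    # every node's backward reads its grad exactly once, before any later
    # accumulation can mutate a shared array.
    if not t.requires_grad:
        return
    if t.grad is None:
        if g.dtype == t.data.dtype and g.flags.owndata and g.flags.writeable:
            t.grad = g
        else:
            t.grad = g.astype(t.data.dtype)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Differentiable operations
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd, _needs(a, b))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd, _needs(a, b))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bwd, _needs(a, b))


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), bwd, a.requires_grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), bwd, _needs(*tensors))


def gather(a: Tensor, index: np.ndarray) -> Tensor:
    """Select rows along axis 0 (``out[i] = a[index[i]]``)."""
    a = _wrap(a)
    index = np.asarray(index)
    out_data = a.data[index]

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        _accum(a, ga)

    return _make(out_data, (a,), bwd, a.requires_grad)


def sum_along(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), bwd, a.requires_grad)


def transpose_last(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.swapaxes(a.data, -1, -2)

    def bwd(g):
        _accum(a, np.swapaxes(g, -1, -2))

    return _make(out_data, (a,), bwd, a.requires_grad)


def softmax_last(a: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax along the last axis, with an optional additive logit mask.

    The mask (e.g. ``-inf`` at padded key positions) is a constant and does
    not receive gradient.
    """
    a = _wrap(a)
    z = a.data + additive_mask if additive_mask is not None else a.data.copy()
    z -= z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    out_data = z

    def bwd(g):
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), bwd, a.requires_grad)


def log_softmax_last(a: Tensor) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def bwd(g):
        _accum(a, g - soft * g.sum(axis=-1, keepdims=True))

    return _make(out_data, (a,), bwd, a.requires_grad)


def layer_norm_last(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable scale/shift."""
    a, gamma, beta = _wrap(a), _wrap(gamma), _wrap(beta)
    mean = a.data.mean(axis=-1, keepdims=True)
    xhat = a.data - mean
    var = np.mean(np.square(xhat), axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=a.data.dtype))
    xhat *= inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        if gamma.requires_grad:
            _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            _accum(beta, _unbroadcast(g, beta.data.shape))
        if a.requires_grad:
            gx = g * gamma.data
            n = a.data.shape[-1]
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(
                axis=-1, keepdims=True
            )
            _accum(a, term * inv)

    return _make(out_data, (a, gamma, beta), bwd, _needs(a, gamma, beta))


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is false or rate is 0."""
    a = _wrap(a)
    if not train or rate <= 0.0:
        return a
    keep = 1.0 - rate
    dtype = a.data.dtype
    u = (rng.random(a.data.shape, dtype=np.float32) if dtype == np.float32
         else rng.random(a.data.shape))
    mask = (u < keep).astype(dtype) / np.asarray(keep, dtype=dtype)
    out_data = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), bwd, a.requires_grad)


# ---------------------------------------------------------------------------
# Backward pass and optimizer
# ---------------------------------------------------------------------------


def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar (or any) output tensor."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
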