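"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's neural coders are small enough to train on a single CPU, so
they run on this self-contained tape-based engine rather than a heavyweight
framework.  Only the operations the coders need are implemented: broadcasting
arithmetic, (batched) matmul, the usual pointwise nonlinearities, reductions,
shape manipulation, embedding gather and (log-)softmax.  Gradients are
accumulated in float64 for run-to-run determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "pow_const",
    "sum_",
    "mean",
    "reshape",
    "swapaxes",
    "concat",
    "embedding",
    "take_along",
    "softmax",
    "log_softmax",
    "getitem",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other, self))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other, self))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(-1.0, self))

    def __sub__(self, other):
        return add(self, -_wrap(other, self))

    def __rsub__(self, other):
        return add(_wrap(other, self), -self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other, self))

    def __getitem__(self, key):
        return getitem(self, key)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node; accumulates into `.grad` of leaves."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward_fn is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward_fn(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def _wrap(x, like: "Tensor | None" = None) -> Tensor:
    """Wrap a constant; python scalars adopt `like`'s dtype to avoid upcasts."""
    if isinstance(x, Tensor):
        return x
    if like is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(x)


def tensor(data) -> Tensor:
    """A constant (non-trainable) tensor."""
    return Tensor(data)


def parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor(out, (a, b), bwd)


def sigmoid(a: Tensor) -> Tensor:
    with np.errstate(over="ignore"):  # saturated tails flush cleanly to 0/1
        out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)

    def bwd(g):
        return (g * (1.0 - out * out),)

    return Tensor(out, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0.0)

    def bwd(g):
        return (g * (a.data > 0.0),)

    return Tensor(out, (a,), bwd)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)

    def bwd(g):
        return (g * out,)

    return Tensor(out, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out = np.log(a.data)

    def bwd(g):
        return (g / a.data,)

    return Tensor(out, (a,), bwd)


def pow_const(a: Tensor, p: float) -> Tensor:
    out = a.data ** p

    def bwd(g):
        return (g * p * a.data ** (p - 1.0),)

    return Tensor(out, (a,), bwd)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor(out, (a,), bwd)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), _wrap(1.0 / n, a))


def reshape(a: Tensor, shape) -> Tensor:
    out = a.data.reshape(shape)

    def bwd(g):
        return (g.reshape(a.data.shape),)

    return Tensor(out, (a,), bwd)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    out = np.swapaxes(a.data, ax1, ax2)

    def bwd(g):
        return (np.swapaxes(g, ax1, ax2),)

    return Tensor(out, (a,), bwd)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), bwd)


def embedding(weight: Tensor, idx) -> Tensor:
    """Row gather: out[..., :] = weight[idx[...], :]."""
    idx = np.asarray(idx)
    out = weight.data[idx]

    def bwd(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx, g)
        return (gw,)

    return Tensor(out, (weight,), bwd)


def take_along(a: Tensor, idx, axis: int = -1) -> Tensor:
    """Gather along `axis` with integer index array `idx` (kept dims)."""
    idx = np.asarray(idx)
    out = np.take_along_axis(a.data, idx, axis=axis)

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, g, axis=axis)
        return (ga,)

    return Tensor(out, (a,), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((g - dot) * out,)

    return Tensor(out, (a,), bwd)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def bwd(g):
        sm = np.exp(out)
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, (a,), bwd)


def _is_basic_index(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return all(isinstance(p, (int, slice, type(Ellipsis), type(None))) for p in parts)


def getitem(a: Tensor, key) -> Tensor:
    out = a.data[key]
    basic = _is_basic_index(key)  # basic indexing never repeats elements

    def bwd(g):
        ga = np.zeros_like(a.data)
        if basic:
            ga[key] += g
        else:
            np.add.at(ga, key, g)
        return (ga,)

    return Tensor(out, (a,), bwd)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class Adam:
    """Adam / AdamW over a list of parameter tensors.

    With ``decoupled=True`` weight decay is applied directly to the weights
    (AdamW); otherwise ``weight_decay`` is ignored.
    """

    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decoupled: bool = False,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.decoupled and self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
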