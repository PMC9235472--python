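"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (two graph layers, a dense adapter and a
two-layer label GCN), so rather than depending on a deep-learning framework it
runs on a compact tape-based autodiff engine: a :class:`Tensor` wraps an
``ndarray`` together with the closure that routes gradients to its parents.
Only the operations the model needs are implemented, each with an analytically
derived backward rule that is checked against finite differences in the test
suite.

All arrays are float64; the graphs involved have at most a few hundred nodes,
so numerical robustness is worth more than memory here.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "transpose",
    "relu",
    "leaky_relu",
    "concat",
    "max_rows",
    "mean_rows",
    "masked_row_softmax",
    "bce_with_logits_mean",
    "Adam",
    "glorot_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape.

    Leaf tensors created with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), constant(-1.0)))

    @property
    def T(self):
        return transpose(self)

    def backward(self) -> None:
        """Backpropagate from this scalar through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# primitives


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def transpose(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(g.T)

    return Tensor(a.data.T, _parents=(a,), _backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return Tensor(a.data * mask, _parents=(a,), _backward=backward)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    factor = np.where(a.data > 0, 1.0, slope)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * factor)

    return Tensor(a.data * factor, _parents=(a,), _backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def max_rows(a: Tensor) -> Tensor:
    """Column-wise max over axis 0, keeping a (1, d) row. Ties route the
    gradient to the first maximal row (NumPy argmax convention)."""
    idx = np.argmax(a.data, axis=0)
    out_data = a.data[idx, np.arange(a.data.shape[1])][None, :]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[idx, np.arange(a.data.shape[1])] = g[0]
            a.accumulate(ga)

    return Tensor(out_data, _parents=(a,), _backward=backward)


def mean_rows(a: Tensor) -> Tensor:
    """Column-wise mean over axis 0, keeping a (1, d) row."""
    n = a.data.shape[0]
    out_data = a.data.mean(axis=0, keepdims=True)

    def backward(g):
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g / n, a.data.shape).copy())

    return Tensor(out_data, _parents=(a,), _backward=backward)


def masked_row_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean); entries outside the
    mask are exactly zero. Rows with an empty mask stay all-zero."""
    m = np.asarray(mask, dtype=bool)
    shifted = np.where(m, scores.data, -np.inf)
    row_max = np.max(shifted, axis=1, keepdims=True)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    ex = np.where(m, np.exp(shifted - row_max), 0.0)
    denom = ex.sum(axis=1, keepdims=True)
    out_data = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)

    def backward(g):
        if scores.requires_grad:
            inner = (g * out_data).sum(axis=1, keepdims=True)
            scores.accumulate(out_data * (g - inner))

    return Tensor(out_data, _parents=(scores,), _backward=backward)


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for large |x|
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits_mean(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with logits over every cell.

    loss = mean_i [ y_i * softplus(-x_i) + (1 - y_i) * softplus(x_i) ]
    with d loss / d x_i = (sigmoid(x_i) - y_i) / n.
    """
    y = np.asarray(targets, dtype=np.float64)
    x = logits.data
    cells = y.size
    loss = (y * _softplus(-x) + (1.0 - y) * _softplus(x)).sum() / cells

    def backward(g):
        if logits.requires_grad:
            logits.accumulate(g * (_sigmoid(x) - y) / cells)

    return Tensor(loss, _parents=(logits,), _backward=backward)


# ---------------------------------------------------------------------------
# parameter initialisation and optimiser


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimiser over a flat list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
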