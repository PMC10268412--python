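"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoders build one computation graph per sentence; graphs are small
(hundreds of nodes), so a dynamic tape with Python-level ops is fast
enough on one CPU while keeping every gradient exact in float64.

Only the primitives the encoders need are provided.  All tensors are
0-d scalars, 1-d vectors or 2-d matrices; broadcasting is restricted to
scalar-with-array, which keeps the backward rules simple and auditable.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "concat",
    "tanh",
    "sigmoid",
    "leaky_relu",
    "log",
    "softmax",
    "vsum",
    "dot",
    "pick",
    "scale",
    "sum_tensors",
]


class Tensor:
    """A node in the computation graph: a value plus its backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- NumPy interop -------------------------------------------------
    def __array__(self, dtype=None, copy=None):
        arr = self.data
        if dtype is not None:
            arr = arr.astype(dtype)
        return np.array(arr) if copy else arr

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return pick(self, idx)

    # -- backprop ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the graph."""
        if grad is None:
            if self.data.shape != ():
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.array(1.0)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: parses can be deep
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` (scalar-vs-array broadcasting)."""
    if g.shape == shape:
        return g
    if shape == ():
        return np.sum(g)
    raise ValueError(f"cannot reduce grad of shape {g.shape} to {shape}")


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    out._backward = backward if out.requires_grad else None
    return out


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data - b.data, (a, b))

    def backward(g):
        _accum(a, g)
        _accum(b, -g)

    out._backward = backward if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    out._backward = backward if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    """Matrix @ vector (or matrix @ matrix)."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        if b.data.ndim == 1:
            _accum(a, np.outer(g, b.data))
            _accum(b, a.data.T @ g)
        else:
            _accum(a, g @ b.data.T)
            _accum(b, a.data.T @ g)

    out._backward = backward if out.requires_grad else None
    return out


def concat(parts: Sequence) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts]), tuple(parts))
    sizes = [p.data.shape[0] for p in parts]

    def backward(g):
        off = 0
        for p, n in zip(parts, sizes):
            _accum(p, g[off : off + n])
            off += n

    out._backward = backward if out.requires_grad else None
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    out = Tensor(y, (a,))

    def backward(g):
        _accum(a, g * (1.0 - y * y))

    out._backward = backward if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, (a,))

    def backward(g):
        _accum(a, g * y * (1.0 - y))

    out._backward = backward if out.requires_grad else None
    return out


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, negative_slope)
    out = Tensor(a.data * mask, (a,))

    def backward(g):
        _accum(a, g * mask)

    out._backward = backward if out.requires_grad else None
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), (a,))

    def backward(g):
        _accum(a, g / a.data)

    out._backward = backward if out.requires_grad else None
    return out


def softmax(a) -> Tensor:
    """Numerically stable softmax over a 1-d score vector."""
    a = as_tensor(a)
    z = a.data - np.max(a.data)
    e = np.exp(z)
    y = e / np.sum(e)
    out = Tensor(y, (a,))

    def backward(g):
        _accum(a, y * (g - np.dot(g, y)))

    out._backward = backward if out.requires_grad else None
    return out


def vsum(a) -> Tensor:
    """Sum of all components -> scalar."""
    a = as_tensor(a)
    out = Tensor(np.sum(a.data), (a,))

    def backward(g):
        _accum(a, np.full_like(a.data, float(g)))

    out._backward = backward if out.requires_grad else None
    return out


def dot(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.dot(a.data, b.data), (a, b))

    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    out._backward = backward if out.requires_grad else None
    return out


def pick(a, idx) -> Tensor:
    """Index a 1-d tensor, returning a scalar tensor."""
    a = as_tensor(a)
    out = Tensor(a.data[idx], (a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    out._backward = backward if out.requires_grad else None
    return out


def scale(s, v) -> Tensor:
    """Scalar tensor times vector tensor."""
    return mul(s, v)


def sum_tensors(ts: Iterable) -> Tensor:
    """Sum an iterable of same-shaped tensors; empty -> scalar 0."""
    acc: Tensor | None = None
    for t in ts:
        acc = as_tensor(t) if acc is None else add(acc, t)
    return acc if acc is not None else Tensor(0.0)
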