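"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core every model in the framework trains on.  A
:class:`Tensor` wraps an ``ndarray`` and records the operations applied to it;
:meth:`Tensor.backward` runs the reverse pass over the recorded graph in
topological order.  The op set is deliberately small: dense algebra
(``matmul``, broadcast arithmetic), pointwise nonlinearities, reductions, and
the two sparse primitives graph networks need — row ``gather`` and
``segment_sum`` (scatter-add) — which together express message passing,
attention softmaxes and pooling.

All computation is float64 and, for a fixed graph, bit-deterministic: the
same inputs and parameters always produce the same outputs and gradients.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: ArrayLike) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def back(g: np.ndarray) -> None:
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))
        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def back(g: np.ndarray) -> None:
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))
        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        a = self

        def back(g: np.ndarray) -> None:
            a._accum(g * p * a.data ** (p - 1.0))
        return Tensor._make(a.data ** p, (a,), back)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def back(g: np.ndarray) -> None:
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)
        return Tensor._make(a.data @ b.data, (a, b), back)

    # -- pointwise ----------------------------------------------------------

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def back(g: np.ndarray) -> None:
            a._accum(g * out_data)
        return Tensor._make(out_data, (a,), back)

    def log(self) -> "Tensor":
        a = self

        def back(g: np.ndarray) -> None:
            a._accum(g / a.data)
        return Tensor._make(np.log(a.data), (a,), back)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def back(g: np.ndarray) -> None:
            a._accum(g * (1.0 - out_data ** 2))
        return Tensor._make(out_data, (a,), back)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def back(g: np.ndarray) -> None:
            a._accum(g * out_data * (1.0 - out_data))
        return Tensor._make(out_data, (a,), back)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def back(g: np.ndarray) -> None:
            a._accum(g * mask)
        return Tensor._make(a.data * mask, (a,), back)

    def silu(self) -> "Tensor":
        a = self
        sig = 1.0 / (1.0 + np.exp(-a.data))

        def back(g: np.ndarray) -> None:
            a._accum(g * (sig + a.data * sig * (1.0 - sig)))
        return Tensor._make(a.data * sig, (a,), back)

    # -- shaping and reductions ----------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        a = self
        old = a.shape

        def back(g: np.ndarray) -> None:
            a._accum(g.reshape(old))
        return Tensor._make(a.data.reshape(*shape), (a,), back)

    def transpose(self) -> "Tensor":
        a = self

        def back(g: np.ndarray) -> None:
            a._accum(g.T)
        return Tensor._make(a.data.T, (a,), back)

    def sum(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        a = self

        def back(g: np.ndarray) -> None:
            if axis is None:
                a._accum(np.full(a.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())
        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def __getitem__(self, key) -> "Tensor":
        a = self

        def back(g: np.ndarray) -> None:
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)
        return Tensor._make(a.data[key], (a,), back)

    # -- sparse primitives ----------------------------------------------------

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Select rows; gradient scatter-adds back."""
        a = self
        idx = np.asarray(idx, dtype=int)

        def back(g: np.ndarray) -> None:
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._make(a.data[idx], (a,), back)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows into ``num_segments`` buckets (scatter-add)."""
        a = self
        ids = np.asarray(segment_ids, dtype=int)
        out_shape = (num_segments,) + a.shape[1:]
        data = np.zeros(out_shape)
        np.add.at(data, ids, a.data)

        def back(g: np.ndarray) -> None:
            a._accum(g[ids])
        return Tensor._make(data, (a,), back)

    # -- backward pass --------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = [Tensor._coerce(t) for t in tensors]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g: np.ndarray) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([p.data for p in parts], axis=axis), parts, back)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [Tensor._coerce(t) for t in tensors]

    def back(g: np.ndarray) -> None:
        for i, p in enumerate(parts):
            p._accum(np.take(g, i, axis=axis))
    return Tensor._make(np.stack([p.data for p in parts], axis=axis), parts, back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax over variable-size groups given by ``segment_ids`` (scores is 1-D
    or (n, 1)); weights within each group are nonnegative and sum to one."""
    ids = np.asarray(segment_ids, dtype=int)
    flat = scores if scores.ndim == 1 else scores.reshape(scores.shape[0])
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, ids, flat.data)
    e = (flat - seg_max[ids]).exp()
    denom = e.segment_sum(ids, num_segments)
    return e / denom.gather(ids)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - np.asarray(target, dtype=np.float64)
    return (diff * diff).mean()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy for integer class labels; logits (n, n_classes)."""
    labels = np.asarray(labels, dtype=int)
    p = softmax(logits, axis=1)
    picked = p.gather(np.arange(len(labels)))[np.arange(len(labels)), labels]
    return -(picked.log().mean())
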