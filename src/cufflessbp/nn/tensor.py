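"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, sized for the 1-D
convolutional / recurrent models in this package: every operation builds a
node holding its inputs and a closure that accumulates gradients into them.
``Tensor.backward()`` runs the tape in reverse topological order.

Only the operations the blood-pressure model needs are provided; all of them
support numpy broadcasting where that is meaningful, with gradients reduced
back to the operand shapes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Back-propagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recurrences unroll into long tapes
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(
            self.data + other.data,
            (self, other),
            lambda g: (self._accum(g), other._accum(g)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return Tensor._node(
            self.data * other.data,
            (self, other),
            lambda g: (self._accum(g * other.data), other._accum(g * self.data)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        return Tensor._node(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._node(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def bwd(g):
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            elif a.ndim == 3 and b.ndim == 2:
                # (B, L, K) @ (K, M): the common batched-affine case
                self._accum(g @ b.T)
                other._accum(np.tensordot(a, g, axes=([0, 1], [0, 1])))
            else:  # pragma: no cover - not used by the model
                raise NotImplementedError("matmul ranks", a.ndim, b.ndim)

        return Tensor._node(a @ b, (self, other), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        y = np.exp(self.data)
        return Tensor._node(y, (self,), lambda g: self._accum(g * y))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: self._accum(g / self.data))

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._node(y, (self,), lambda g: self._accum(g * 0.5 / y))

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._node(y, (self,), lambda g: self._accum(g * (1.0 - y * y)))

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable logistic
        return Tensor._node(y, (self,), lambda g: self._accum(g * y * (1.0 - y)))

    def relu(self):
        mask = self.data > 0
        return Tensor._node(
            np.where(mask, self.data, 0.0), (self,), lambda g: self._accum(g * mask)
        )

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax positions."""
        y = self.data.max(axis=axis, keepdims=True)
        mask = self.data == y
        # split ties evenly so the gradient check stays clean
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        out = y if keepdims else np.squeeze(y, axis=axis)
        return Tensor._node(out, (self,), bwd)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g: self._accum(g.reshape(orig))
        )

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,), lambda g: self._accum(g.transpose(inv))
        )

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._node(self.data[idx], (self,), bwd)

    def pad(self, pad_width, value: float = 0.0):
        """Constant-pad; gradient is the complementary slice."""
        pw = tuple((int(a), int(b)) for a, b in pad_width)

        def bwd(g):
            sl = tuple(slice(a, g.shape[i] - b) for i, (a, b) in enumerate(pw))
            self._accum(g[sl])

        return Tensor._node(
            np.pad(self.data, pw, constant_values=value), (self,), bwd
        )

    def softmax(self, axis: int = -1):
        """Softmax along an axis (composed from primitive ops)."""
        shifted = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    ts = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._node(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)
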