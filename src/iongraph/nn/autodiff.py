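"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine supports exactly the operations the graph-network stack needs:
broadcast arithmetic, matrix products, ReLU-family activations, reductions,
row gather/scatter and segment sums (the message-passing primitives).
Gradients are accumulated by topological traversal of the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "leaky_relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape),
                    _unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = backward
        return out

    # -- elementwise functions ----------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0.0, self.data, alpha * self.data),
                     parents=(self,))
        out._backward = lambda g: (
            g * np.where(self.data > 0.0, 1.0, alpha),)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: (g * 0.5 / out.data,)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = (self.data.size if axis is None else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structural ops ------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def take(self, indices: np.ndarray):
        """Gather rows (axis 0)."""
        indices = np.asarray(indices)
        out = Tensor(self.data[indices], parents=(self,))

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, indices, g)
            return (acc,)
        out._backward = backward
        return out

    def put(self, indices: np.ndarray, n_rows: int):
        """Scatter own rows into a zero matrix of `n_rows` rows (inverse
        of :meth:`take` with unique indices)."""
        indices = np.asarray(indices)
        data = np.zeros((n_rows,) + self.data.shape[1:], dtype=np.float64)
        data[indices] = self.data
        out = Tensor(data, parents=(self,))
        out._backward = lambda g: (g[indices],)
        return out

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Sum rows into `num_segments` buckets (scatter-add on axis 0)."""
        segment_ids = np.asarray(segment_ids)
        data = np.zeros((num_segments,) + self.data.shape[1:],
                        dtype=np.float64)
        np.add.at(data, segment_ids, self.data)
        out = Tensor(data, parents=(self,))
        out._backward = lambda g: (g[segment_ids],)
        return out

    # -- backprop ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a "
                                 "scalar output")
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
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def spmm(matrix, x: Tensor, matrix_t=None) -> Tensor:
    """Sparse-constant × dense-tensor product: `matrix @ x`.

    `matrix` is a fixed scipy sparse matrix (graph structure, not a
    learnable quantity); the gradient flows through `x` only.  Pass the
    pre-transposed matrix to avoid rebuilding it on every call.
    """
    if matrix_t is None:
        matrix_t = matrix.T.tocsr()
    out = Tensor(matrix @ x.data, parents=(x,))
    out._backward = lambda g: (matrix_t @ g,)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def relu(t: Tensor) -> Tensor:
    return t.relu()


def leaky_relu(t: Tensor, alpha: float = 0.2) -> Tensor:
    return t.leaky_relu(alpha)
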