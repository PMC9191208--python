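"""A minimal tape-based reverse-mode automatic differentiation engine.

Just enough ops for the graph network: matmul, broadcasting arithmetic,
row gather/scatter (segment sums for message aggregation), concatenation,
ELU, sigmoid, square root and means.  Gradients are accumulated on leaf
:class:`Tensor` objects created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(float)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward)

    def __sub__(self, other):
        other = as_tensor(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return self._make(self.data - other.data, (self, other), backward)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __neg__(self):
        return self * -1.0

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return as_tensor(other) - self

    def matmul(self, other: "Tensor") -> "Tensor":
        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return self._make(self.data @ other.data, (self, other), backward)

    def square(self) -> "Tensor":
        def backward(g):
            return (2.0 * g * self.data,)

        return self._make(self.data**2, (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g / (2.0 * out_data),)

        return self._make(out_data, (self,), backward)

    # ---- reductions -------------------------------------------------
    def mean0(self) -> "Tensor":
        """Mean over axis 0, keeping the axis (for batch statistics)."""
        n = self.data.shape[0]

        def backward(g):
            return (np.broadcast_to(g / n, self.shape).copy(),)

        return self._make(self.data.mean(axis=0, keepdims=True), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            return (np.full(self.shape, float(g) / n),)

        return self._make(self.data.mean(), (self,), backward)

    # ---- nonlinearities ---------------------------------------------
    def elu(self) -> "Tensor":
        clipped = np.minimum(self.data, 0.0)
        out_data = np.maximum(self.data, 0.0) + np.expm1(clipped)

        def backward(g):
            return (g * np.where(self.data > 0, 1.0, np.exp(clipped)),)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    # ---- indexing / shaping -----------------------------------------
    def gather_rows(self, idx: np.ndarray, scatter=None) -> "Tensor":
        """Row selection; ``scatter`` is an optional precomputed sparse
        (n_rows, len(idx)) incidence matrix used for the backward pass."""
        idx = np.asarray(idx)

        def backward(g):
            if scatter is not None:
                return (scatter @ g,)
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), backward)

    def segment_sum(self, idx: np.ndarray, n_segments: int, scatter=None) -> "Tensor":
        """Scatter-add rows into ``n_segments`` buckets given by ``idx``."""
        idx = np.asarray(idx)
        if scatter is not None:
            out_data = scatter @ self.data
        else:
            out_data = np.zeros((n_segments,) + self.data.shape[1:], dtype=self.data.dtype)
            np.add.at(out_data, idx, self.data)

        def backward(g):
            return (g[idx],)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    # ---- graph traversal --------------------------------------------
    def backward(self, grad=None) -> None:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves reached directly (e.g. self is a leaf)
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=float)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused affine map ``x @ W + b``."""
    out = Tensor(x.data @ W.data + b.data)
    if x.requires_grad or W.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (x, W, b)
        out._backward = lambda g: (g @ W.data.T, x.data.T @ g, g.sum(axis=0))
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization over axis 0.

    Returns (output, batch_mean, batch_var) with the statistics as plain
    arrays for running-average updates.
    """
    mu = x.data.mean(axis=0)
    var = x.data.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(gamma.data * xhat + beta.data)
    if x.requires_grad or gamma.requires_grad or beta.requires_grad:
        n = x.data.shape[0]

        def backward(g):
            gxhat = g * gamma.data
            gx = inv_std * (
                gxhat
                - gxhat.mean(axis=0)
                - xhat * (gxhat * xhat).mean(axis=0)
            )
            return gx, (g * xhat).sum(axis=0), g.sum(axis=0)

        out.requires_grad = True
        out._parents = (x, gamma, beta)
        out._backward = backward
    return out, mu, var


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out
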