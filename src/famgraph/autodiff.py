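"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the extraction model needs: broadcasting
arithmetic, (batched) matrix products, pointwise nonlinearities, reductions,
concatenation, slicing/gathering, masked max, and log-softmax.  Gradients
are accumulated by a topological-order sweep from the loss node.  All
operators are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction ------------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data
        if a.ndim < 2:
            raise ValueError("matmul left operand must be at least 2-D")

        def backward(g):
            if self.requires_grad:
                if b.ndim == 1:  # matrix-vector: out[...,i] = sum_k a[...,i,k] b[k]
                    ga = np.expand_dims(g, -1) * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._acc(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if b.ndim == 1:
                    gb = (np.expand_dims(g, -1) * a).reshape(-1, a.shape[-1]).sum(0)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._acc(_unbroadcast(gb, b.shape))

        return Tensor._node(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._acc(g * (1.0 - y * y))

        return Tensor._node(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._acc(g * y * (1.0 - y))

        return Tensor._node(y, (self,), backward)

    def relu(self):
        y = np.maximum(self.data, 0.0)

        def backward(g):
            self._acc(g * (self.data > 0))

        return Tensor._node(y, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        y = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._acc(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._node(y, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int):
        """Max along one axis; gradient flows to the (first) argmax."""
        y = self.data.max(axis=axis)
        idx = self.data.argmax(axis=axis)

        def backward(g):
            gx = np.zeros_like(self.data)
            grid = np.indices(y.shape)
            index = list(grid)
            index.insert(axis if axis >= 0 else self.data.ndim + axis, idx)
            np.add.at(gx, tuple(index), g)
            self._acc(gx)

        return Tensor._node(y, (self,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        y = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            self._acc(g.reshape(orig))

        return Tensor._node(y, (self,), backward)

    def swapaxes(self, a: int, b: int):
        y = np.swapaxes(self.data, a, b)

        def backward(g):
            self._acc(np.swapaxes(g, a, b))

        return Tensor._node(y, (self,), backward)

    def __getitem__(self, key):
        y = self.data[key]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self._acc(gx)

        return Tensor._node(y, (self,), backward)

    def log_softmax(self, axis: int):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        p = np.exp(y)

        def backward(g):
            self._acc(g - p * g.sum(axis=axis, keepdims=True))

        return Tensor._node(y, (self,), backward)

    # -- autograd driver ----------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    y = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._acc(g[tuple(sl)])

    return Tensor._node(y, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    y = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, i, axis=axis))

    return Tensor._node(y, tuple(tensors), backward)


def gather(t: Tensor, index: tuple) -> Tensor:
    """Fancy-index gather with gradient scatter-add (for NLL picking)."""
    return t[index]


def where_mask(t: Tensor, mask: np.ndarray, fill: float) -> Tensor:
    """Replace entries where ``mask`` is False by ``fill`` (no grad there)."""
    y = np.where(mask, t.data, fill)

    def backward(g):
        t._acc(np.where(mask, g, 0.0))

    return Tensor._node(y, (t,), backward)


def dropout(t: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or p == 0."""
    if not train or p <= 0.0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)
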