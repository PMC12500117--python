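"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff core supporting exactly the operations the
encoder, contrastive objective and internal-coordinate losses need:
broadcasting arithmetic, matmul, reductions, elementwise transcendentals
(including ``arccos`` and ``arctan2`` for bond angles and dihedrals),
slicing/stacking, and a numerically stable softmax/log-sum-exp.

Gradients are accumulated by topological-order backward passes from a scalar
loss.  All tensors are float64; this package favours reproducibility and
gradient fidelity over speed, and the molecules it trains on are small.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "stack", "concat", "cross", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort (graphs can be deep)
        topo = []
        visited = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack_.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
        # leave .grad populated on leaves

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def bw(g):
            self._accum(-g)

        out._backward = bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accum(np.outer(g, other.data) if self.data.ndim == 2 else g * other.data)
                else:
                    self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2), self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accum(np.outer(self.data, g) if other.data.ndim == 2 else self.data * g)
                else:
                    other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ----------------------------------------------------------
    def _unary(self, fval, dval):
        out = self._make(fval, (self,), None)

        def bw(g):
            self._accum(g * dval)

        out._backward = bw if out.requires_grad else None
        return out

    def exp(self):
        v = np.exp(self.data)
        return self._unary(v, v)

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def sqrt(self):
        v = np.sqrt(self.data)
        return self._unary(v, 0.5 / v)

    def tanh(self):
        v = np.tanh(self.data)
        return self._unary(v, 1.0 - v**2)

    def sigmoid(self):
        v = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(v, v * (1.0 - v))

    def relu(self):
        return self._unary(np.maximum(self.data, 0.0), (self.data > 0).astype(np.float64))

    def arccos(self):
        return self._unary(np.arccos(self.data), -1.0 / np.sqrt(1.0 - self.data**2))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float64)
        return self._unary(np.clip(self.data, lo, hi), mask)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)

        def bw(g):
            self._accum(g.reshape(old))

        out._backward = bw if out.requires_grad else None
        return out

    @property
    def T(self):
        out = self._make(self.data.T, (self,), None)

        def bw(g):
            self._accum(g.T)

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw if out.requires_grad else None
        return out

    # -- composites -----------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        out = ((self - m).exp().sum(axis=axis, keepdims=True)).log() + m
        if not keepdims:
            out = out.reshape(np.squeeze(out.data, axis=axis).shape)
        return out

    def norm(self, axis=-1, keepdims=False, eps: float = 0.0):
        sq = (self * self).sum(axis=axis, keepdims=keepdims)
        if eps:
            sq = sq + eps
        return sq.sqrt()

    def l2_normalize(self, axis=-1, eps: float = 1e-12):
        return self / (self.norm(axis=axis, keepdims=True, eps=eps))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return data if isinstance(data, Tensor) else Tensor(data, requires_grad)


def arctan2(y: Tensor, x: Tensor) -> Tensor:
    """Elementwise two-argument arctangent with gradients to both arguments."""
    y = tensor(y)
    x = tensor(x)
    val = np.arctan2(y.data, x.data)
    out = Tensor(val)
    if y.requires_grad or x.requires_grad:
        out.requires_grad = True
        out._parents = (y, x)
        denom = x.data**2 + y.data**2

        def bw(g):
            if y.requires_grad:
                y._accum(_unbroadcast(g * x.data / denom, y.data.shape))
            if x.requires_grad:
                x._accum(_unbroadcast(-g * y.data / denom, x.data.shape))

        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in ts], axis=axis))
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)

        def bw(g):
            pieces = np.split(g, len(ts), axis=axis)
            for t, piece in zip(ts, pieces):
                if t.requires_grad:
                    t._accum(np.squeeze(piece, axis=axis))

        out._backward = bw
    return out


def concat(tensors, axis=0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis))
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bw
    return out


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Cross product along the last axis (length 3), built from slices."""
    a, b = tensor(a), tensor(b)
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return stack(
        [ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1
    )


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
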