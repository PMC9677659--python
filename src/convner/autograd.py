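"""Minimal reverse-mode automatic differentiation on numpy arrays.

All model layers (convolutions, BiLSTM, CRF loss) are composed from the
small op set defined here.  Arrays are float64 throughout so that the
finite-difference gradient checks in the test-suite can use tight
tolerances.  The engine is deliberately simple: a :class:`Tensor` records
its parents and a backward closure; :meth:`Tensor.backward` runs an
iterative topological sweep accumulating gradients into ``.grad``.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "stack", "logsumexp", "gather2", "gather_labels"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological order (graphs from LSTM loops can be deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, n: float):
        out = Tensor(self.data ** n, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * n * self.data ** (n - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        """Matrix product; supports (…,C) @ (C,D) with the left operand
        2-D or 3-D and the right operand 2-D."""
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        x, w = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ w.T)
            if other.requires_grad:
                if x.ndim == 2:
                    other._accum(x.T @ g)
                else:  # (B, L, C) @ (C, D): contract batch and length
                    other._accum(np.tensordot(x, g, axes=([0, 1], [0, 1])))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = bwd
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def gelu(self):
        """x * Phi(x) with Phi the exact standard-normal CDF (erf form)."""
        x = self.data
        phi = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accum(g * (phi + x * pdf))

        out._backward = bwd
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    def pad_length(self, left: int, right: int):
        """Zero-pad along axis 1 (the sequence axis of a (B, L, C) map)."""
        if left == 0 and right == 0:
            return self
        width = [(0, 0)] * self.data.ndim
        width[1] = (left, right)
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))
        L = self.data.shape[1]

        def bwd(g):
            if self.requires_grad:
                sl = [slice(None)] * self.data.ndim
                sl[1] = slice(left, left + L)
                self._accum(g[tuple(sl)])

        out._backward = bwd
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def logsumexp(x: Tensor, axis: int) -> Tensor:
    """Numerically stable log-sum-exp reduction; gradient is the softmax."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = np.exp(x.data - m).sum(axis=axis, keepdims=True)
    val = np.log(s) + m
    out = Tensor(np.squeeze(val, axis=axis), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            soft = np.exp(x.data - val)
            x._accum(np.expand_dims(g, axis) * soft)

    out._backward = bwd
    return out


def gather2(m: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """m[rows, cols] for a 2-D tensor and integer index arrays."""
    out = Tensor(m.data[rows, cols], m.requires_grad, (m,))

    def bwd(g):
        if m.requires_grad:
            full = np.zeros_like(m.data)
            np.add.at(full, (rows, cols), g)
            m._accum(full)

    out._backward = bwd
    return out


def gather_labels(e: Tensor, labels: np.ndarray) -> Tensor:
    """Select e[b, t, labels[b, t]] from a (B, L, K) emission tensor."""
    B, L, _ = e.data.shape
    bi = np.arange(B)[:, None]
    ti = np.arange(L)[None, :]
    out = Tensor(e.data[bi, ti, labels], e.requires_grad, (e,))

    def bwd(g):
        if e.requires_grad:
            full = np.zeros_like(e.data)
            np.add.at(full, (bi, ti, labels), g)
            e._accum(full)

    out._backward = bwd
    return out
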