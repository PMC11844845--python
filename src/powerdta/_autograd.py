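"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the affinity model trains on: a small tape-based
autodiff engine exposing exactly the primitives the architecture needs
(broadcasting arithmetic, batched matmul, 1-D convolution, embedding lookup,
masked softmax / max / mean reductions) plus an Adam optimizer.  Everything
is float64; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d_same",
    "embedding",
    "masked_max",
    "masked_mean",
    "masked_softmax",
    "relu",
    "sigmoid",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._bw = bw

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

    # ---- graph traversal ----

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            if node._bw is not None:
                node._bw(node.grad)
            # free the tape as we go
            node._parents = ()
            node._bw = None

    # ---- arithmetic ----

    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data + other.data, (self, other))

            def bw(g, a=self, b=other):
                a._acc(_unbroadcast(g, a.shape))
                b._acc(_unbroadcast(g, b.shape))

        else:
            c = np.asarray(other, dtype=np.float64)
            out = Tensor(self.data + c, (self,))

            def bw(g, a=self):
                a._acc(_unbroadcast(g, a.shape))

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def bw(g, a=self):
            a._acc(-g)

        out._bw = bw
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, (self, other))

            def bw(g, a=self, b=other):
                a._acc(_unbroadcast(g * b.data, a.shape))
                b._acc(_unbroadcast(g * a.data, b.shape))

        else:
            c = np.asarray(other, dtype=np.float64)
            out = Tensor(self.data * c, (self,))

            def bw(g, a=self):
                a._acc(_unbroadcast(g * c, a.shape))

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g, a=self, b=other):
            a._acc(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            b._acc(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        out._bw = bw
        return out

    def __pow__(self, p):
        p = float(p)
        out = Tensor(self.data**p, (self,))

        def bw(g, a=self):
            a._acc(g * p * a.data ** (p - 1.0))

        out._bw = bw
        return out

    # ---- shape ----

    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g, a=self):
            a._acc(g.reshape(old))

        out._bw = bw
        return out

    # ---- reductions ----

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g, a=self):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._acc(np.broadcast_to(g, a.shape).copy())

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def bw(g, a=x):
        a._acc(g * (a.data > 0))

    out._bw = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, (x,))

    def bw(g, a=x):
        a._acc(g * y * (1.0 - y))

    out._bw = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, ts=tuple(tensors)):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._acc(piece)

    out._bw = bw
    return out


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup: (V, E) table indexed by an integer array."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], (table,))

    def bw(g, tab=table):
        if tab.grad is None:
            tab.grad = np.zeros_like(tab.data)
        np.add.at(tab.grad, idx.reshape(-1), g.reshape(-1, tab.data.shape[1]))

    out._bw = bw
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor, kernel: int = 3) -> Tensor:
    """1-D convolution over axis 1 with zero 'same' padding.

    x: (B, L, C_in); w: (kernel*C_in, C_out); b: (C_out,).
    """
    B, L, cin = x.data.shape
    pad = kernel // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    cols = np.concatenate([xp[:, i : i + L, :] for i in range(kernel)], axis=2)
    out = Tensor(cols @ w.data + b.data, (x, w, b))

    def bw(g, a=x, wt=w, bt=b):
        cout = g.shape[-1]
        wt._acc(cols.reshape(-1, kernel * cin).T @ g.reshape(-1, cout))
        bt._acc(g.sum(axis=(0, 1)))
        dcols = g @ wt.data.T
        dxp = np.zeros_like(xp)
        for i in range(kernel):
            dxp[:, i : i + L, :] += dcols[:, :, i * cin : (i + 1) * cin]
        a._acc(dxp[:, pad : pad + L, :])

    out._bw = bw
    return out


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    """Softmax along `axis`, restricted to positions where `mask` is true.

    Masked positions get exactly zero weight.  Computed with the standard
    max-subtraction stabilization.  `mask` must broadcast to x.shape and
    every softmax slice must contain at least one true entry.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.data.shape)
    xm = np.where(mask, x.data, -np.inf)
    m = xm.max(axis=axis, keepdims=True)
    e = np.where(mask, np.exp(xm - m), 0.0)
    s = e.sum(axis=axis, keepdims=True)
    if np.any(s == 0):
        raise ValueError("masked_softmax: a slice has no unmasked positions")
    y = e / s
    out = Tensor(y, (x,))

    def bw(g, a=x):
        a._acc(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._bw = bw
    return out


def masked_max(x: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    """Max along `axis` over unmasked positions (gradient to the argmax)."""
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.data.shape)
    xm = np.where(mask, x.data, -np.inf)
    arg = xm.argmax(axis=axis)
    out = Tensor(np.take_along_axis(xm, np.expand_dims(arg, axis), axis).squeeze(axis), (x,))

    def bw(g, a=x):
        gz = np.zeros_like(a.data)
        np.put_along_axis(gz, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis)
        a._acc(gz)

    out._bw = bw
    return out


def masked_mean(x: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.data.shape).astype(np.float64)
    n = mask.sum(axis=axis, keepdims=True)
    if np.any(n == 0):
        raise ValueError("masked_mean: a slice has no unmasked positions")
    y = (x.data * mask).sum(axis=axis, keepdims=True) / n
    out = Tensor(y.squeeze(axis), (x,))

    def bw(g, a=x):
        a._acc(np.expand_dims(g, axis) * mask / n)

    out._bw = bw
    return out


class Adam:
    """Adam optimizer over a name -> Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
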