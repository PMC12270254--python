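"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the graph-attention model: a small tape
machine supporting exactly the operations the model needs — dense linear
algebra, elementwise nonlinearities, row gather, and segment (scatter) sums,
from which edge-softmax attention is composed. Gradients are accumulated by
topological traversal of the recorded graph; correctness is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "concat", "segment_sum", "gather", "Adam"]

# scatter-add as a cached sparse matmul: the same edge-index arrays are reused
# every epoch, and csr @ dense is far faster than np.add.at
_scatter_cache: dict = {}


def _scatter_matrix(idx: np.ndarray, n: int) -> sp.csr_matrix:
    key = (idx.tobytes(), n)
    S = _scatter_cache.get(key)
    if S is None:
        if len(_scatter_cache) > 64:
            _scatter_cache.clear()
        S = sp.csr_matrix((np.ones(len(idx)), (idx, np.arange(len(idx)))),
                          shape=(n, len(idx)))
        _scatter_cache[key] = S
    return S


def _scatter_add(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    if vals.ndim == 1:
        return np.bincount(idx, weights=vals, minlength=n)
    return _scatter_matrix(idx, n) @ vals


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Run reverse-mode accumulation from this (typically scalar) node."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        ex = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        val = np.where(pos, self.data, ex)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.where(pos, 1.0, ex + alpha))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is zero outside [lo, hi] (hard clip)."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: self._accumulate(g * inside)
        return out

    # -- reductions / shaping --------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g / n, self.data.shape))
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def Parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather along axis 0: out[i] = t[idx[i]]."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], parents=(t,))
    out._backward = lambda g: t._accumulate(_scatter_add(idx, g, t.data.shape[0]))
    return out


def segment_sum(t: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of `t` into `num_segments` buckets: out[s] = Σ_{idx[i]=s} t[i]."""
    idx = np.asarray(idx)
    out = Tensor(_scatter_add(idx, t.data, num_segments), parents=(t,))
    out._backward = lambda g: t._accumulate(g[idx])
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


class Adam:
    """ADAM optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
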