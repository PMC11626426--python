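"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autodiff engine providing exactly the operations the graph
network regressors need: broadcasting arithmetic, matrix products, ReLU/SiLU
nonlinearities, row gather (``take``) and segment-sum scatter, and reductions.
Parameters are :class:`Tensor` objects with ``requires_grad=True``; the Adam
optimizer updates them in place.

Everything is float64 and deterministic given a seeded ``numpy`` generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "relu", "silu", "segment_sum", "segment_mean",
           "take", "concat", "mse", "Adam", "Linear", "MLP"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -----------------------------------------------------
    def backward(self) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- ops -----------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.shape))

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, parents=(self,), backward=bwd)

    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g) / n))

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def silu(x: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = x.data * sig

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (sig + out * (1.0 - sig)))

    return Tensor(out, parents=(x,), backward=bwd)


def _scatter_rows(rows: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Sum 2-D ``rows`` into ``n`` buckets by ``idx`` (bincount-backed)."""
    if rows.ndim == 1:
        return np.bincount(idx, weights=rows, minlength=n)
    d = rows.shape[1]
    flat = (idx[:, None] * d + np.arange(d)).ravel()
    return np.bincount(flat, weights=rows.ravel(), minlength=n * d).reshape(n, d)


def take(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: out[k] = x[idx[k]]."""
    idx = np.asarray(idx, dtype=np.intp)

    def bwd(g):
        if x.requires_grad:
            x._accum(_scatter_rows(g, idx, x.data.shape[0]))

    return Tensor(x.data[idx], parents=(x,), backward=bwd)


def segment_sum(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-add rows of x into n_segments buckets: out[s] = sum_{idx[k]=s} x[k]."""
    idx = np.asarray(idx, dtype=np.intp)
    out = _scatter_rows(x.data, idx, n_segments)

    def bwd(g):
        if x.requires_grad:
            x._accum(g[idx])

    return Tensor(out, parents=(x,), backward=bwd)


def segment_mean(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-mean: segment_sum divided by per-segment counts (empty -> 0)."""
    idx = np.asarray(idx, dtype=np.intp)
    counts = np.maximum(np.bincount(idx, minlength=n_segments), 1).astype(float)
    out = _scatter_rows(x.data, idx, n_segments)
    out = out / counts[:, None] if out.ndim == 2 else out / counts

    def bwd(g):
        if x.requires_grad:
            gc = g / counts[:, None] if g.ndim == 2 else g / counts
            x._accum(gc[idx])

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


class Linear:
    """Dense layer with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class MLP:
    def __init__(self, dims: list[int], rng: np.random.Generator, activation=relu):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.activation(x)
        return x

    @property
    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_snapshot(self, snap: list[np.ndarray]) -> None:
        for p, s in zip(self.params, snap):
            p.data = s.copy()
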