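"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains several small neural models (a transformer encoder for
contextual KG embeddings, its distilled student, translational baseline
scorers, and the multilabel diagnosis networks).  All of them run at desk
scale, so instead of a heavyweight deep-learning framework they share this
small tape-based autodiff layer: a :class:`Tensor` wraps a float ndarray
(float32 or float64; the parameters' dtype is preserved end to end),
records its parents, and :meth:`Tensor.backward` walks the graph in reverse
topological order.  Ops are deliberately coarse (matmul, softmax, layer-norm
statistics) so graphs stay short and the heavy lifting happens inside NumPy.

Everything is deterministic: the only randomness (dropout, parameter init)
comes from `numpy.random.Generator` objects passed in by callers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "gather_rows",
    "concat",
    "softmax",
    "log_softmax",
    "layer_norm",
    "gelu",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        # Accumulation never mutates in place, so storing `g` without a copy
        # is fine: all later contributions build fresh arrays.
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- shape / dtype sugar -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # keep python scalars weak-typed
            other = float(other)
            def sbwd(g):
                if self.requires_grad:
                    self._accum(g)
            return Tensor._make(self.data + other, (self,), sbwd)
        other = as_tensor(other)
        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            other = float(other)
            def sbwd(g):
                if self.requires_grad:
                    self._accum(g * other)
            return Tensor._make(self.data * other, (self,), sbwd)
        other = as_tensor(other)
        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        return Tensor._make(self.data ** exponent, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        if b.ndim == 2 and a.ndim > 2:
            # x @ W with batched x: flatten to one large GEMM, and compute
            # dW as a single (k, N) @ (N, n) product instead of per-sample
            # outer products that would then be broadcast-reduced.
            k, n = b.shape
            out_shape = a.shape[:-1] + (n,)
            out_data = (a.reshape(-1, k) @ b).reshape(out_shape)
            def bwd(g):
                g2 = g.reshape(-1, n)
                if self.requires_grad:
                    self._accum((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accum(a.reshape(-1, k).T @ g2)
            return Tensor._make(out_data, (self, other), bwd)
        def bwd(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(b, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(a, -1, -2) @ g)
        return Tensor._make(a @ b, (self, other), bwd)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bwd)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)
        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        return Tensor._make(np.abs(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))
        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))
        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        return Tensor._make(np.maximum(self.data, 0.0), (self,), bwd)

    def cos(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g * np.sin(self.data))
        return Tensor._make(np.cos(self.data), (self,), bwd)

    def sin(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.cos(self.data))
        return Tensor._make(np.sin(self.data), (self,), bwd)

    # -- backward ------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structured ops ---------------------------------------------------------


def gather_rows(table: Tensor, idx) -> Tensor:
    """Index rows of a 2-D tensor: result shape = idx.shape + (row_dim,)."""
    idx = np.asarray(idx, dtype=np.intp)
    if table.ndim != 2:
        raise ValueError("gather_rows expects a 2-D table")
    row_dim = table.data.shape[1]
    def bwd(g):
        if table.requires_grad:
            buf = np.zeros_like(table.data)
            np.add.at(buf, idx.ravel(), g.reshape(-1, row_dim))
            table._accum(buf)
    return Tensor._make(table.data[idx], (table,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum(sizes)[:-1]
    def bwd(g):
        parts = np.split(g, offsets, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)
    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    def bwd(g):
        if x.requires_grad:
            x._accum((g - (g * s).sum(axis=axis, keepdims=True)) * s)
    return Tensor._make(s, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    def bwd(g):
        if x.requires_grad:
            x._accum(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))
    return Tensor._make(out_data, (x,), bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (fused analytic backward)."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    centered = xd - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out_data = xhat * gain.data + bias.data
    def bwd(g):
        if x.requires_grad:
            gx = g * gain.data
            dx = (gx - gx.mean(axis=-1, keepdims=True)
                  - xhat * (gx * xhat).mean(axis=-1, keepdims=True)) * inv
            x._accum(dx)
        if gain.requires_grad:
            gain._accum((g * xhat).reshape(-1, xd.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, xd.shape[-1]).sum(axis=0))
    return Tensor._make(out_data, (x, gain, bias), bwd)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    xd = x.data
    x2 = xd * xd
    t = np.tanh(_GELU_C * (xd + 0.044715 * (x2 * xd)))
    out_data = 0.5 * xd * (1.0 + t)
    def bwd(g):
        if x.requires_grad:
            du = _GELU_C * (1.0 + 0.134145 * x2)
            dx = 0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * du
            x._accum(g * dx)
    return Tensor._make(out_data, (x,), bwd)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused affine map x @ W + b over the last axis (batched x)."""
    k, n = W.data.shape
    xd = x.data
    out_shape = xd.shape[:-1] + (n,)
    x2 = xd.reshape(-1, k)
    out_data = (x2 @ W.data + b.data).reshape(out_shape)
    def bwd(g):
        g2 = g.reshape(-1, n)
        if x.requires_grad:
            x._accum((g2 @ W.data.T).reshape(xd.shape))
        if W.requires_grad:
            W._accum(x2.T @ g2)
        if b.requires_grad:
            b._accum(g2.sum(axis=0))
    return Tensor._make(out_data, (x, W, b), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p == 0 or no generator is supplied."""
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.data.shape, dtype=np.float32) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer with bias correction over a list of parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
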