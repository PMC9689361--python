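"""A small vectorized reverse-mode automatic-differentiation engine.

Tensors wrap numpy arrays and record the operations applied to them;
``Tensor.backward()`` accumulates exact gradients by reverse traversal of
the tape. The operation set is deliberately minimal - elementwise algebra,
matrix products, sigmoid, reductions, indexing/scatter, products with
constant sparse matrices, and a differentiable sparse linear solve whose
backward pass is the adjoint system (a solve with the transposed matrix) -
which is everything the physics-informed reconstruction needs: network
forward passes, forward-propagated spatial derivatives, windowed SSIM
losses, and backpropagation through the stabilized-EPT solve.

An Adam optimizer (bias-corrected first/second moments) is included.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

__all__ = ["Tensor", "sigmoid", "concatenate", "sparse_mm", "sparse_solve", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_own_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev
        self._own_grad = False

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        # first contribution is adopted without copying; in-place addition is
        # only ever applied to an array allocated here, never to a borrowed one
        if self.grad is None:
            self.grad = g
            self._own_grad = False
        elif self._own_grad:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._own_grad = True

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise algebra ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions / shaping ----------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.broadcast_to(g, self.data.shape).copy()
        )
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def __getitem__(self, key):
        """Gather by slices, boolean masks or *duplicate-free* index arrays."""
        out = Tensor(self.data[key], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g  # valid because keys never repeat an element
                self._accum(full)

        out._backward = bw
        return out

    # -- autodiff driver ----------------------------------------------------
    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def sigmoid(t: Tensor) -> Tensor:
    """Numerically stable logistic function."""
    s = expit(t.data)
    out = Tensor(s, _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def sparse_mm(S: sp.spmatrix, t: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a tensor (1-D or 2-D)."""
    S = S.tocsr()
    out = Tensor(S @ t.data, _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(S.T @ g)

    out._backward = bw
    return out


def sparse_solve(
    values: Tensor, rows: np.ndarray, cols: np.ndarray, n: int, rhs: Tensor
) -> Tensor:
    """Differentiable solve of ``A x = b`` with ``A`` given in COO triplets.

    Forward: sparse LU factorization and solve. Backward (adjoint method):
    with incoming gradient ``gbar``, solve ``A^T lam = gbar``; then
    ``d/db = lam`` and ``d/dA_ij = -lam_i x_j`` evaluated on the sparsity
    pattern only. Gradients are exact for any scalar loss of the solution.

    Raises ``RuntimeError`` on singular systems.
    """
    A = sp.csc_matrix((values.data, (rows, cols)), shape=(n, n))
    lu = spla.splu(A)
    x = lu.solve(rhs.data)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("sparse_solve: non-finite solution (singular system?)")
    out = Tensor(x, _prev=(values, rhs))

    def bw(g):
        lam = lu.solve(g, trans="T")
        if rhs.requires_grad:
            rhs._accum(lam)
        if values.requires_grad:
            values._accum(-lam[rows] * x[cols])

    out._backward = bw
    return out


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = [0] * len(self.params)  # per-parameter step counts
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:  # parameters without gradient are untouched
                continue
            self.t[i] += 1
            t = self.t[i]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**t)
            vhat = self.v[i] / (1 - self.b2**t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
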