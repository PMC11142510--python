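"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in this package is small (patch-sized inputs, a few tens of
thousands of parameters), so rather than depending on a deep-learning
framework the layers are expressed with a compact tape-based autodiff
engine: a :class:`Tensor` wraps an ``ndarray``, records the operations that
produced it, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.

Only the operations the model needs are provided (broadcasted arithmetic,
matmul, reshape/transpose/pad/gather/concat, reductions, and the pointwise
nonlinearities behind the Smish activation).  Convolutions are *not*
primitives here: the layer code lowers them to gather + matmul, which keeps
the engine tiny and every gradient testable by finite differences.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "sigmoid", "smish_core"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _coerce(self, other) -> "Tensor":
        # python scalars adopt this tensor's dtype so float32 graphs stay
        # float32 (a bare np.asarray would promote everything to float64)
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor.as_tensor(other)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._coerce(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        x = self.data

        def backward(g):
            return (g * exponent * np.power(x, exponent - 1.0),)

        return Tensor._make(np.power(x, exponent), (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        """Matrix product; supports (…, m, k) @ (k, n) and (m, k) @ (k, n)."""
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            if b.ndim == 2 and a.ndim > 2:
                # one flat GEMM instead of a batched product + reduction
                gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            else:
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (_unbroadcast(ga, a.shape), gb)

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def pad(self, pad_width: Sequence[tuple[int, int]]) -> "Tensor":
        """Zero-pad; ``pad_width`` as for :func:`numpy.pad`."""
        pw = [tuple(p) for p in pad_width]
        slices = tuple(slice(lo, lo + n) for (lo, _), n in zip(pw, self.data.shape))
        return Tensor._make(np.pad(self.data, pw), (self,),
                            lambda g: (g[slices],))

    def gather_cols(self, index: np.ndarray, scatter=None) -> "Tensor":
        """Fancy-index axis 1 of a 2-D tensor: out[i, ...] = self[i, index].

        ``index`` may have any shape; the result has shape
        ``(n,) + index.shape``.  This is the primitive the conv layers use
        for im2col lowering; its adjoint is a scatter-add, executed as a
        sparse matmul when the caller supplies the precomputed ``scatter``
        matrix from :func:`build_scatter`.
        """
        if self.data.ndim != 2:
            raise ValueError("gather_cols expects a 2-D tensor")
        n, f = self.data.shape
        out_data = self.data[:, index]

        def backward(g):
            g2 = np.ascontiguousarray(g.reshape(n, -1))
            if scatter is not None:
                return ((scatter @ g2.T).T,)
            gx = np.zeros((n, f), dtype=g.dtype)
            np.add.at(gx, (slice(None), index), g.reshape(n, *index.shape))
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape),)
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, axes)
            return (np.broadcast_to(g, shape),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- pointwise nonlinearities --------------------------------------------
    def clamp_min(self, lo: float) -> "Tensor":
        mask = (self.data > lo)
        return Tensor._make(np.maximum(self.data, lo), (self,),
                            lambda g: (g * mask,))

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def log1p(self) -> "Tensor":
        x = self.data
        return Tensor._make(np.log1p(x), (self,), lambda g: (g / (1.0 + x),))

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every requires-grad leaf."""
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor with no grad path")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward without grad requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if p._backward is None:  # leaf parameter
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        pieces = []
        for lo, hi in zip(offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pieces.append(g[tuple(sl)])
        return tuple(pieces)

    return Tensor._make(out_data, ts, backward)


def build_scatter(index: np.ndarray, n_features: int):
    """Sparse (F, nnz) adjoint of the gather defined by ``index``."""
    from scipy import sparse

    flat = np.asarray(index).ravel()
    nnz = flat.size
    return sparse.csr_matrix(
        (np.ones(nnz, dtype=np.float32), (flat, np.arange(nnz))),
        shape=(n_features, nnz))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe in both tails
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(x: Tensor) -> Tensor:
    return Tensor.as_tensor(x).sigmoid()


def smish_core(x: Tensor) -> Tensor:
    """Smish activation x * tanh(log1p(sigmoid(x))) on the autodiff tape.

    Implemented as one fused node: with s = sigmoid(x) and
    t = tanh(log1p(s)), the derivative is t + x (1 - t^2) s (1 - s) / (1 + s).
    """
    x = Tensor.as_tensor(x)
    s = _sigmoid(x.data)
    t = np.tanh(np.log1p(s))
    out = x.data * t

    def backward(g):
        return (g * (t + x.data * (1.0 - t * t) * s * (1.0 - s) / (1.0 + s)),)

    return Tensor._make(out, (x,), backward)
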