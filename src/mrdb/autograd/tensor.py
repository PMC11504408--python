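"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient
and a backward closure.  Calling :meth:`Tensor.backward` on a scalar output
walks the recorded graph in reverse topological order and accumulates
gradients into every tensor created with ``requires_grad=True``.

Only the primitives required by the segmentation network are provided;
broadcasting is supported everywhere by summing gradients back to the
operand's shape.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "einsum2",
    "linear_scan",
    "where_scalar",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with reverse-mode autodiff support."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # keep numpy from broadcasting element-wise over Tensor operands;
    # reflected operators (__rmul__ etc.) handle ndarray-on-the-left.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: Sequence["Tensor"] = ()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = tuple(_prev)

    # ---------------------------------------------------------------- misc
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape).astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    @property
    def _needs(self) -> bool:
        return self.requires_grad or self._prev != () or self._backward is not None

    def _like(self, other) -> "Tensor":
        """Wrap ``other`` as a Tensor without silently promoting dtype
        (Python scalars adopt this tensor's dtype)."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 or arr.dtype.kind in "iub":
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    # ----------------------------------------------------------- operators
    def __add__(self, other):
        other = self._like(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self._needs:
                self._accum(g)
            if other._needs:
                other._accum(g)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._like(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self._needs:
                self._accum(g * other.data)
            if other._needs:
                other._accum(g * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._like(other))

    def __rsub__(self, other):
        return self._like(other) + (-self)

    def __truediv__(self, other):
        other = self._like(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self._needs:
                self._accum(g / other.data)
            if other._needs:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._like(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            if self._needs:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _bw
        return out

    # --------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * 0.5 / out.data)

        out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * np.sign(self.data))

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def _bw(g):
            if self._needs:
                self._accum(g * mask)

        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self):
        d = self.data
        s = np.empty_like(d)
        pos = d >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        s[~pos] = e / (1.0 + e)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(self.data * s, _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        out._backward = _bw
        return out

    def softplus(self):
        d = self.data
        out_d = np.logaddexp(0.0, d)
        out = Tensor(out_d, _prev=(self,))
        s = 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))

        def _bw(g):
            if self._needs:
                self._accum(g * s)

        out._backward = _bw
        return out

    # ----------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(g.transpose(inv))

        out._backward = _bw
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), _prev=(self,))

        def _bw(g):
            if self._needs:
                self._accum(np.flip(g, axis=axis))

        out._backward = _bw
        return out

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def _bw(g):
            if not self._needs:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
                return
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- matmul
    def matmul(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self._needs:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other._needs:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = _bw
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), _prev=ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t._needs:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in ts], axis=axis), _prev=ts)

    def _bw(g):
        for i, t in enumerate(ts):
            if t._needs:
                t._accum(np.take(g, i, axis=axis))

    out._backward = _bw
    return out


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Every index must appear in at least two of the three subscript groups
    (no diagonals, no free summed indices), which holds for all uses in
    this package.
    """
    a, b = as_tensor(a), as_tensor(b)
    lhs, sub_o = subscripts.split("->")
    sub_a, sub_b = lhs.split(",")
    out = Tensor(np.einsum(subscripts, a.data, b.data, optimize=True), _prev=(a, b))

    def _bw(g):
        if a._needs:
            a._accum(np.einsum(f"{sub_o},{sub_b}->{sub_a}", g, b.data, optimize=True))
        if b._needs:
            b._accum(np.einsum(f"{sub_o},{sub_a}->{sub_b}", g, a.data, optimize=True))

    out._backward = _bw
    return out


def where_scalar(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select between two tensors by a constant boolean mask."""
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out = Tensor(np.where(cond, a.data, b.data), _prev=(a, b))

    def _bw(g):
        if a._needs:
            a._accum(np.where(cond, g, 0.0))
        if b._needs:
            b._accum(np.where(cond, 0.0, g))

    out._backward = _bw
    return out


def linear_scan(a: Tensor, b: Tensor) -> Tensor:
    """First-order linear recurrence ``h[t] = a[t] * h[t-1] + b[t]``, ``h[-1] = 0``.

    ``a`` and ``b`` have shape ``(M, L)``; the recurrence runs along the last
    axis independently for every row.  This is the computational core of the
    selective state-space scan; both forward and backward are sequential
    loops over ``L`` vectorized over ``M``.
    """
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape or a.data.ndim != 2:
        raise ValueError(f"linear_scan expects matching (M, L) inputs, got {a.shape} and {b.shape}")
    # time-major internal layout keeps every per-step slice contiguous
    ad = np.ascontiguousarray(a.data.T)
    bd = np.ascontiguousarray(b.data.T)
    L = ad.shape[0]
    ht = np.empty_like(bd)
    prev = np.zeros(ad.shape[1], dtype=bd.dtype)
    for t in range(L):
        prev = ad[t] * prev + bd[t]
        ht[t] = prev
    out = Tensor(np.ascontiguousarray(ht.T), _prev=(a, b))

    def _bw(g):
        gt_ = np.ascontiguousarray(g.T)
        ga = np.empty_like(ad) if a._needs else None
        gb = np.empty_like(bd) if b._needs else None
        acc = np.zeros(ad.shape[1], dtype=g.dtype)
        for t in range(L - 1, -1, -1):
            acc = acc + gt_[t]
            if gb is not None:
                gb[t] = acc
            if ga is not None:
                ga[t] = acc * (ht[t - 1] if t > 0 else 0.0)
            acc = acc * ad[t]
        if ga is not None:
            a._accum(np.ascontiguousarray(ga.T))
        if gb is not None:
            b._accum(np.ascontiguousarray(gb.T))

    out._backward = _bw
    return out
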