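"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal define-by-run tape: every operation builds a :class:`Tensor`
holding its value, its parents and a closure that propagates the upstream
gradient.  ``Tensor.backward()`` runs the tape in reverse topological
order.  Only the operations the segmentation network needs are provided
(broadcast arithmetic, matmul, reductions, reshape/transpose, softmax,
leaky-ReLU, log/exp/pow, clip, concatenate, 3D convolution and 2x2x2
transposed convolution).

A process-global multiply counter can be armed with
:func:`count_multiplies`; matmul and convolution record the number of
scalar multiplications they perform, which supports empirical complexity
checks (e.g. that linear-projection attention scales as O(n*p)).
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv3d",
    "conv_transpose3d",
    "count_multiplies",
]


class MultiplyCounter:
    """Accumulates scalar-multiplication counts while armed."""

    def __init__(self) -> None:
        self.count = 0


_ACTIVE_COUNTERS: list[MultiplyCounter] = []


@contextlib.contextmanager
def count_multiplies():
    """Context manager yielding a :class:`MultiplyCounter` armed within."""
    counter = MultiplyCounter()
    _ACTIVE_COUNTERS.append(counter)
    try:
        yield counter
    finally:
        _ACTIVE_COUNTERS.remove(counter)


def _record_muls(n: int) -> None:
    if _ACTIVE_COUNTERS:
        for c in _ACTIVE_COUNTERS:
            c.count += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @classmethod
    def _make(cls, data: np.ndarray, parents: Iterable["Tensor"], backward) -> "Tensor":
        out = cls(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; seeds with ones for scalars."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = a.data ** exponent

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = np.matmul(a.data, b.data)
        # each output element is an inner product of length k (batched)
        k = a.data.shape[-1]
        _record_muls(out_data.size * k)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -- reductions and shape ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        out_data = a.data.transpose(axes)
        inverse = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inverse))

        return Tensor._make(out_data, (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    # -- elementwise nonlinearities ------------------------------------
    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside the range only."""
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(out_data, (a,), backward)

    def leaky_relu(self, slope: float = 0.01):
        a = self
        out_data = np.where(a.data >= 0, a.data, slope * a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * np.where(a.data >= 0, 1.0, slope).astype(g.dtype))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        return self.leaky_relu(0.0)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# 3D convolution primitives
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3D cross-correlation of ``x`` (N,Ci,D,H,W) with ``w`` (Co,Ci,k,k,k).

    Implemented as im2col + matmul; the column matrix is kept alive in
    the backward closure, trading memory for speed.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, ci, d, h, wd = x.shape
    co, ci_w, k, _, _ = w.shape
    if ci != ci_w:
        raise ValueError(f"input has {ci} channels but kernel expects {ci_w}")
    names = "DHW"
    for ax, ext in zip(names, (d, h, wd)):
        if ext % stride != 0:
            raise ValueError(
                f"axis {ax} of extent {ext} is not divisible by stride {stride}"
            )
    xd = x.data
    if padding:
        pad = ((0, 0), (0, 0)) + ((padding, padding),) * 3
        xd = np.pad(xd, pad)
    do = (d + 2 * padding - k) // stride + 1
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    L = do * ho * wo
    # gather columns one kernel offset at a time: 27 regular slab copies
    # beat a single strided 8-D gather by a wide margin
    cols = np.empty((n, ci, k, k, k, L), dtype=xd.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                slab = xd[:, :, i:i + stride * do:stride,
                          j:j + stride * ho:stride,
                          l:l + stride * wo:stride]
                cols[:, :, i, j, l, :] = slab.reshape(n, ci, L)
    cols = cols.reshape(n, ci * k ** 3, L)
    wmat = w.data.reshape(co, ci * k ** 3)
    out = np.matmul(wmat, cols)  # (N, Co, L)
    _record_muls(out.size * ci * k ** 3)
    if b is not None:
        out = out + b.data.reshape(1, co, 1)
    out = out.reshape(n, co, do, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, co, L)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gm, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gm)  # (N, Ci*k^3, L)
            gcols = gcols.reshape(n, ci, k, k, k, L)
            dp, hp, wp = (d + 2 * padding, h + 2 * padding, wd + 2 * padding)
            gx = np.zeros((n, ci, dp, hp, wp), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gx[:, :, i:i + stride * do:stride,
                           j:j + stride * ho:stride,
                           l:l + stride * wo:stride] += \
                            gcols[:, :, i, j, l, :].reshape(n, ci, do, ho, wo)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gx)

    return Tensor._make(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed 3D convolution with kernel and stride 2 (no overlap).

    ``x``: (N,Ci,D,H,W); ``w``: (Ci,Co,2,2,2); output (N,Co,2D,2H,2W).
    With stride == kernel the output decomposes into an einsum followed
    by an interleaving reshape.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, ci, d, h, wd = x.shape
    ci_w, co, k, _, _ = w.shape
    if ci != ci_w:
        raise ValueError(f"input has {ci} channels but kernel expects {ci_w}")
    if k != 2:
        raise ValueError("only kernel/stride 2 transposed convolution is supported")
    out = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data)
    _record_muls(x.data.size * co * k ** 3)
    out = out.reshape(n, co, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gr = g.reshape(n, co, d, 2, h, 2, wd, 2)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.einsum("ncdhw,nodihjwk->coijk", x.data, gr)
            w._accumulate(gw)
        if x.requires_grad:
            gx = np.einsum("nodihjwk,coijk->ncdhw", gr, w.data)
            x._accumulate(gx)

    return Tensor._make(out, parents, backward)
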