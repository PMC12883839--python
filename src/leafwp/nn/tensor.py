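"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs the chain rule through the recorded graph.
The op set is exactly what the spectral networks in this package need:
broadcasted arithmetic, (batched) matmul, exp/log/relu, reductions, reshape
and transpose, softmax, and 1-D (depthwise) convolution. Everything is
float64 — at the problem sizes involved (hundreds of spectra, 176 bands)
the precision is cheap and makes gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "conv1d", "depthwise_conv1d", "dropout"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for long loops
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _sum_to_shape(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ------------------------------------------------------
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

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._node(a.data**p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._node(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._node(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._node(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (a,), backward)

    # -- reductions and shape ops ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._node(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(*inv))

        return Tensor._node(a.data.transpose(*axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift is a constant w.r.t. the graph)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def _same_pad(x: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    p = (k - 1) // 2
    return np.pad(x, ((0, 0), (0, 0), (p, k - 1 - p))), p


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1-D cross-correlation with 'same' padding.

    x: (B, C_in, L); w: (C_out, C_in, k) with k odd; b: (C_out,).
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, k = w.data.shape
    if Cin_w != Cin:
        raise ValueError(f"conv1d channel mismatch: input {Cin}, weight {Cin_w}")
    xp, p = _same_pad(x.data, k)
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)  # (B,Cin,L,k)
    out_data = np.einsum("oik,bilk->bol", w.data, windows, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bol,bilk->oik", g, windows, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dwin = np.einsum("bol,oik->bilk", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + L] += dwin[:, :, :, j]
            x._accumulate(dxp[:, :, p : p + L])

    return Tensor._node(out_data, parents, backward)


def depthwise_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel 1-D convolution ('same' padding). w: (C, k); b: (C,)."""
    B, C, L = x.data.shape
    C_w, k = w.data.shape
    if C_w != C:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {C_w}")
    xp, p = _same_pad(x.data, k)
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)  # (B,C,L,k)
    out_data = np.einsum("ck,bclk->bcl", w.data, windows, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bcl,bclk->ck", g, windows, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dwin = np.einsum("bcl,ck->bclk", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + L] += dwin[:, :, :, j]
            x._accumulate(dxp[:, :, p : p + L])

    return Tensor._node(out_data, parents, backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
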