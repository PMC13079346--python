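"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autograd: each :class:`Tensor` wraps an
``ndarray`` and records a closure that propagates gradients to its parents.
Only the operations needed by the models in this package are implemented
(broadcast arithmetic, matmul, reductions, softmax, GELU, im2col convolution,
2x2 max pooling, bilinear resizing). Gradients are dense float64.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected array-like, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- op helper
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
                else:
                    gg = g[..., None, :] if a.ndim == 1 else g
                    ga = gg @ np.swapaxes(b, -1, -2)
                    if a.ndim == 1:
                        ga = ga[..., 0, :]
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.outer(a, g) if b.ndim == 2 else a[..., None] * g
                else:
                    gg = g[..., None] if b.ndim == 1 else g
                    gb = np.swapaxes(a, -1, -2) @ gg
                    if b.ndim == 1:
                        gb = gb[..., 0]
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(np.float64))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------- shape changes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    @staticmethod
    def cat(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        return Tensor._make(out_data, tuple(tensors), backward)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        """Tanh-approximate GELU (the convention used by ViT/MAE stacks)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
                self._accum(g * d)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._make(s, (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), backward)

    # ---------------------------------------------------------- image ops
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2D convolution, NCHW layout, via im2col.

        weight: (C_out, C_in, kh, kw).
        """
        x = self.data
        n, cin, h, w = x.shape
        cout, cin_w, kh, kw = weight.shape
        assert cin == cin_w, "channel mismatch"
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        hp, wp = xp.shape[2], xp.shape[3]
        h2 = (hp - kh) // stride + 1
        w2 = (wp - kw) // stride + 1
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, cin, kh, kw, h2, w2),
            strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
            writeable=False,
        )
        cols2 = cols.reshape(n, cin * kh * kw, h2 * w2)
        wmat = weight.data.reshape(cout, cin * kh * kw)
        out = np.einsum("ok,nkp->nop", wmat, cols2, optimize=True)
        out = out.reshape(n, cout, h2, w2)
        if bias is not None:
            out = out + bias.data[None, :, None, None]

        def backward(g):
            gmat = g.reshape(n, cout, h2 * w2)
            if weight.requires_grad:
                gw = np.einsum("nop,nkp->ok", gmat, cols2, optimize=True)
                weight._accum(gw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = np.einsum("ok,nop->nkp", wmat, gmat, optimize=True)
                gcols = gcols.reshape(n, cin, kh, kw, h2, w2)
                gx = np.zeros((n, cin, hp, wp))
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + h2 * stride : stride,
                           j : j + w2 * stride : stride] += gcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even dims"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max in each window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2)
        mask = mask.transpose(0, 1, 2, 4, 3, 5)

        def backward(g):
            if self.requires_grad:
                gx = mask * g[:, :, :, None, :, None]
                self._accum(gx.reshape(n, c, h, w))

        return Tensor._make(out, (self,), backward)

    def upsample_nearest2x(self) -> "Tensor":
        x = self.data
        out = x.repeat(2, axis=-2).repeat(2, axis=-1)
        n, c, h, w = x.shape

        def backward(g):
            if self.requires_grad:
                gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
                self._accum(gx)

        return Tensor._make(out, (self,), backward)

    def resize_bilinear(self, out_h: int, out_w: int) -> "Tensor":
        """Differentiable bilinear resize of the last two axes."""
        h, w = self.shape[-2], self.shape[-1]
        wr = _interp_matrix(h, out_h)
        wc = _interp_matrix(w, out_w)
        out = np.matmul(np.matmul(wr, self.data), wc.T)

        def backward(g):
            if self.requires_grad:
                self._accum(np.matmul(wr.T, np.matmul(g, wc)))

        return Tensor._make(out, (self,), backward)

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D linear-interpolation matrix (half-pixel centers, edges clamped)."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
    else:
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        m[np.arange(n_out), lo] += 1 - frac
        m[np.arange(n_out), hi] += frac
    _INTERP_CACHE[key] = m
    return m


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    expanded = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors]
    return Tensor.cat(expanded, axis=axis)
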