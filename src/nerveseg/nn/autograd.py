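"""Compact define-by-run reverse-mode autodiff on NumPy arrays.

Float32 tensors, dynamic graph, topological-order backward pass.  Implements
exactly the operator set the segmentation networks and losses need: broadcast
arithmetic, log/exp/sigmoid/clip, reductions, matmul, concatenation, channel
softmax, PReLU, instance normalisation, strided 3D convolution and the
stride-2 transposed convolution.  Convolutions are im2col views contracted
with :func:`numpy.tensordot`, so everything runs on a single CPU with BLAS.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "conv_transpose3d_2x",
    "instance_norm",
    "prelu",
    "relu",
    "sigmoid",
    "softmax",
]

ArrayLike = Union["Tensor", np.ndarray, float, int]


class Tensor:
    """A float32 array node in a dynamic computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to our reflected operators instead of
    # numpy broadcasting the Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:
                node.grad = g if node.grad is None else node.grad + g

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, key):
        return take(self, key)

    # numpy-style helpers used by the loss code
    def clip(self, lo, hi):
        return clip(self, lo, hi)

    def log(self):
        return log(self)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _wrap(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------


def add(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def mul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return Tensor(a.data * b.data, parents=(a, b), backward=backward)


def div(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape)),
        )

    return Tensor(a.data / b.data, parents=(a, b), backward=backward)


def power(a: ArrayLike, exponent: float) -> Tensor:
    a = _wrap(a)
    e = float(exponent)
    out = a.data ** np.float32(e)

    def backward(g):
        if e == 0.0:
            return ((a, np.zeros_like(a.data)),)
        return ((a, g * e * a.data ** np.float32(e - 1.0)),)

    return Tensor(out, parents=(a,), backward=backward)


def log(a: ArrayLike) -> Tensor:
    a = _wrap(a)

    def backward(g):
        return ((a, g / a.data),)

    return Tensor(np.log(a.data), parents=(a,), backward=backward)


def exp(a: ArrayLike) -> Tensor:
    a = _wrap(a)
    out = np.exp(a.data)

    def backward(g):
        return ((a, g * out),)

    return Tensor(out, parents=(a,), backward=backward)


def clip(a: ArrayLike, lo: float, hi: float) -> Tensor:
    """Clamp; gradient flows only where the input is strictly inside the band."""
    a = _wrap(a)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        return ((a, g * inside),)

    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=backward)


def sigmoid(a: ArrayLike) -> Tensor:
    a = _wrap(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * out * (1.0 - out)),)

    return Tensor(out, parents=(a,), backward=backward)


def relu(a: ArrayLike) -> Tensor:
    a = _wrap(a)
    pos = a.data > 0

    def backward(g):
        return ((a, g * pos),)

    return Tensor(a.data * pos, parents=(a,), backward=backward)


def reduce_sum(a: ArrayLike, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def backward(g):
        g = np.asarray(g, dtype=np.float32)
        if axis is None:
            gg = np.broadcast_to(g, a.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
            gg = np.broadcast_to(g, a.shape)
        return ((a, gg.copy()),)

    return Tensor(out, parents=(a,), backward=backward)


def reduce_mean(a: ArrayLike, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis, keepdims), 1.0 / count)


def reshape(a: ArrayLike, shape) -> Tensor:
    a = _wrap(a)

    def backward(g):
        return ((a, g.reshape(a.shape)),)

    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def take(a: ArrayLike, key) -> Tensor:
    a = _wrap(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return ((a, out),)

    return Tensor(a.data[key], parents=(a,), backward=backward)


def matmul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return Tensor(a.data @ b.data, parents=(a, b), backward=backward)


def concat(tensors: Sequence[ArrayLike], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(ts, parts))

    return Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=ts, backward=backward)


def softmax(a: ArrayLike, axis: int = 1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((a, out * (g - dot)),)

    return Tensor(out, parents=(a,), backward=backward)


def prelu(a: ArrayLike, slope: "Tensor") -> Tensor:
    """Channel-wise parametric ReLU; ``slope`` has shape (C,), input (N,C,...)."""
    a = _wrap(a)
    c = a.shape[1]
    s = slope.data.reshape((1, c) + (1,) * (a.ndim - 2))
    pos = a.data > 0
    out = np.where(pos, a.data, s * a.data)

    def backward(g):
        ga = np.where(pos, g, g * s)
        gs = (g * a.data * ~pos).sum(axis=(0,) + tuple(range(2, a.ndim)))
        return ((a, ga), (slope, gs.astype(np.float32)))

    return Tensor(out, parents=(a, slope), backward=backward)


def instance_norm(a: ArrayLike, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> Tensor:
    """Instance normalisation over spatial axes of an (N, C, D, H, W) tensor."""
    a = _wrap(a)
    axes = tuple(range(2, a.ndim))
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    cshape = (1, a.shape[1]) + (1,) * (a.ndim - 2)
    out = xhat * gamma.data.reshape(cshape) + beta.data.reshape(cshape)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def backward(g):
        gxhat = g * gamma.data.reshape(cshape)
        mean_g = gxhat.mean(axis=axes, keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=axes, keepdims=True)
        ga = inv * (gxhat - mean_g - xhat * mean_gx)
        ggamma = (g * xhat).sum(axis=(0,) + axes)
        gbeta = g.sum(axis=(0,) + axes)
        return (
            (a, ga.astype(np.float32)),
            (gamma, ggamma.astype(np.float32)),
            (beta, gbeta.astype(np.float32)),
        )

    return Tensor(out, parents=(a, gamma, beta), backward=backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def conv3d(
    x: ArrayLike,
    weight: "Tensor",
    bias: Optional["Tensor"] = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """3D convolution of (N, C, D, H, W) with weight (O, C, kz, ky, kx)."""
    x = _wrap(x)
    kz, ky, kx = weight.shape[2:]
    s = int(stride)
    if padding:
        pw = ((0, 0), (0, 0)) + tuple((padding, padding) for _ in range(3))
        xp = np.pad(x.data, pw)
    else:
        xp = x.data
    cols = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    out = np.tensordot(cols, weight.data, axes=((1, 5, 6, 7), (1, 2, 3, 4)))
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1, 1)
    n_out = out.shape[2:]

    def backward(g):
        grads = []
        dw = np.tensordot(g, cols, axes=((0, 2, 3, 4), (0, 2, 3, 4)))
        grads.append((weight, dw.astype(np.float32)))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3, 4)).astype(np.float32)))
        dxp = np.zeros_like(xp)
        for a in range(kz):
            for b in range(ky):
                for c in range(kx):
                    contrib = np.tensordot(g, weight.data[:, :, a, b, c], axes=((1,), (0,)))
                    contrib = np.moveaxis(contrib, -1, 1)
                    dxp[
                        :,
                        :,
                        a : a + s * n_out[0] : s,
                        b : b + s * n_out[1] : s,
                        c : c + s * n_out[2] : s,
                    ] += contrib
        if padding:
            dxp = dxp[:, :, padding:-padding or None, padding:-padding or None, padding:-padding or None]
        grads.append((x, dxp.astype(np.float32)))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, parents=parents, backward=backward)


def conv_transpose3d_2x(x: ArrayLike, weight: "Tensor", bias: Optional["Tensor"] = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    ``x`` is (N, C, D, H, W); ``weight`` is (C, O, 2, 2, 2); output spatial
    dims are doubled.  Kernel-2/stride-2 windows do not overlap, so this is a
    per-voxel linear map followed by block interleaving.
    """
    x = _wrap(x)
    n, c, d, h, w = x.shape
    o = weight.shape[1]
    t = np.tensordot(x.data, weight.data, axes=((1,), (0,)))  # (N,D,H,W,O,2,2,2)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)
    out = np.ascontiguousarray(t.reshape(n, o, 2 * d, 2 * h, 2 * w))
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        gt = g.reshape(n, o, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        # gt: (N,D,H,W,O,2,2,2)
        dw = np.tensordot(x.data, gt, axes=((0, 2, 3, 4), (0, 1, 2, 3)))
        dx = np.tensordot(gt, weight.data, axes=((4, 5, 6, 7), (1, 2, 3, 4)))
        dx = np.moveaxis(dx, -1, 1)
        grads = [(x, dx.astype(np.float32)), (weight, dw.astype(np.float32))]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3, 4)).astype(np.float32)))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, parents=parents, backward=backward)
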