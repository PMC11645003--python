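"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the primitives the volumetric segmentation
networks need: broadcast-aware arithmetic, exp/log/relu, axis reductions,
3D convolution (arbitrary kernel/stride/padding), nearest-neighbour
upsampling and channel concatenation.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.

All data is kept in float32.  Convolution is a register-blocked direct
3D stencil compiled with numba (channels-first layout keeps the depth axis
contiguous for SIMD), which avoids the memory traffic an im2col GEMM would
spend on gather copies at these small channel counts.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numba
import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context in which no computation graph is recorded (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- shape helpers -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g, self=self, orig=orig):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)

        def backward(g, a=self, e=e):
            a._accumulate(g * e * np.power(a.data, e - 1.0))

        return Tensor._make(np.power(self.data, e), (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._accumulate(g * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, mask=mask):
            a._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape

        def backward(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, shape))

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


@numba.njit(fastmath=True, cache=True)
def _conv_forward_kernel(xp, w, s):  # pragma: no cover - exercised via conv3d
    n_, c_, hp, wp, dp = xp.shape
    f_, k = w.shape[0], w.shape[2]
    ho, wo, do = (hp - k) // s + 1, (wp - k) // s + 1, (dp - k) // s + 1
    out = np.zeros((n_, f_, ho, wo, do), dtype=np.float32)
    acc = np.empty(do, dtype=np.float32)
    for n in range(n_):
        for f in range(f_):
            for h in range(ho):
                for ww in range(wo):
                    acc[:] = 0.0
                    for c in range(c_):
                        for i in range(k):
                            for j in range(k):
                                row = xp[n, c, h * s + i, ww * s + j]
                                for l in range(k):
                                    wv = w[f, c, i, j, l]
                                    if s == 1:  # unit stride vectorises
                                        for d in range(do):
                                            acc[d] += wv * row[d + l]
                                    else:
                                        for d in range(do):
                                            acc[d] += wv * row[d * s + l]
                    out[n, f, h, ww] = acc
    return out


@numba.njit(fastmath=True, cache=True)
def _conv_weight_grad_kernel(xp, g, k, s):  # pragma: no cover
    n_, c_, hp, wp, dp = xp.shape
    f_, ho, wo, do = g.shape[1], g.shape[2], g.shape[3], g.shape[4]
    dw = np.zeros((f_, c_, k, k, k), dtype=np.float32)
    for n in range(n_):
        for f in range(f_):
            for c in range(c_):
                for h in range(ho):
                    for ww in range(wo):
                        grow = g[n, f, h, ww]
                        for i in range(k):
                            for j in range(k):
                                xrow = xp[n, c, h * s + i, ww * s + j]
                                for l in range(k):
                                    acc = np.float32(0.0)
                                    if s == 1:  # unit stride vectorises
                                        for d in range(do):
                                            acc += grow[d] * xrow[d + l]
                                    else:
                                        for d in range(do):
                                            acc += grow[d] * xrow[d * s + l]
                                    dw[f, c, i, j, l] += acc
    return dw


def _pad_volume(xd: np.ndarray, p: int) -> np.ndarray:
    if not p:
        return np.ascontiguousarray(xd)
    xp = np.zeros((xd.shape[0], xd.shape[1], xd.shape[2] + 2 * p,
                   xd.shape[3] + 2 * p, xd.shape[4] + 2 * p), dtype=np.float32)
    xp[:, :, p:-p, p:-p, p:-p] = xd
    return xp


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation: x (N,C,H,W,D) with weight (F,C,k,k,k).

    Forward and both backward passes are register-blocked direct
    convolutions (numba kernels); the input gradient is the full correlation
    of the zero-stuffed output gradient with the flipped, channel-swapped
    kernel.
    """
    s, p = int(stride), int(padding)
    f, cw, k = weight.data.shape[0], weight.data.shape[1], weight.data.shape[2]
    if cw != x.data.shape[1]:
        raise ValueError(f"channel mismatch: input {x.data.shape[1]}, weight {cw}")
    xp = _pad_volume(x.data, p)
    n, c, hp, wp, dp = xp.shape
    ho, wo, do = (hp - k) // s + 1, (wp - k) // s + 1, (dp - k) // s + 1
    if min(ho, wo, do) < 1:
        raise ValueError("kernel larger than (padded) input")
    out = _conv_forward_kernel(xp, weight.data, s)
    if bias is not None:
        out += bias.data.reshape(1, f, 1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g, x=x, weight=weight, bias=bias, xp=xp,
                 n=n, c=c, f=f, k=k, s=s, p=p, ho=ho, wo=wo, do=do,
                 hp=hp, wp=wp, dp=dp):
        g = np.ascontiguousarray(g)
        if weight.requires_grad:
            weight._accumulate(_conv_weight_grad_kernel(xp, g, k, s))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            q = k - 1
            gp = np.zeros((n, f, s * (ho - 1) + 1 + 2 * q, s * (wo - 1) + 1 + 2 * q,
                           s * (do - 1) + 1 + 2 * q), dtype=np.float32)
            gp[:, :, q:gp.shape[2] - q:s, q:gp.shape[3] - q:s,
               q:gp.shape[4] - q:s] = g
            wflip = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            gx = _conv_forward_kernel(gp, wflip, 1)
            # trailing rows a strided kernel never visited get zero gradient
            he, we, de = s * (ho - 1) + k, s * (wo - 1) + k, s * (do - 1) + k
            if (he, we, de) != (hp, wp, dp):
                full = np.zeros((n, c, hp, wp, dp), dtype=np.float32)
                full[:, :, :he, :we, :de] = gx
                gx = full
            if p:
                gx = np.ascontiguousarray(gx[:, :, p:-p, p:-p, p:-p])
            x._accumulate(gx)

    return Tensor._make(out, parents, backward)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour ×factor upsampling of a (N,C,H,W,D) tensor."""
    fct = int(factor)
    n, c, h, w, d = x.data.shape
    out = np.broadcast_to(
        x.data.reshape(n, c, h, 1, w, 1, d, 1),
        (n, c, h, fct, w, fct, d, fct),
    ).reshape(n, c, h * fct, w * fct, d * fct)

    def backward(g, x=x, n=n, c=c, h=h, w=w, d=d, fct=fct):
        x._accumulate(g.reshape(n, c, h, fct, w, fct, d, fct).sum(axis=(3, 5, 7)))

    return Tensor._make(out, (x,), backward)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalisation over a channels-last tensor.

    Normalises per channel (axis 1) over batch and spatial axes using batch
    statistics, with an analytic backward pass.  Returns the output tensor
    plus the batch mean and (biased) variance for running-average updates.
    """
    axes = (0, 2, 3, 4)
    bshape = (1, x.data.shape[1], 1, 1, 1)
    mean = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    invstd = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xn = (x.data - mean.reshape(bshape)) * invstd.reshape(bshape)
    out = gamma.data.reshape(bshape) * xn + beta.data.reshape(bshape)

    def backward(g, x=x, gamma=gamma, beta=beta, xn=xn, invstd=invstd,
                 axes=axes, bshape=bshape):
        if gamma.requires_grad:
            gamma._accumulate((g * xn).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gm = g.mean(axis=axes).reshape(bshape)
            gxn = (g * xn).mean(axis=axes).reshape(bshape)
            x._accumulate((gamma.data.reshape(bshape) * invstd.reshape(bshape))
                          * (g - gm - xn * gxn))

    return Tensor._make(out, (x, gamma, beta), backward), mean, var


def softmax_channels(logits: Tensor) -> Tensor:
    """Numerically stable softmax over the channel axis (axis 1)."""
    shift = logits.data.max(axis=1, keepdims=True)  # constant shift, gradient-neutral
    e = (logits - Tensor(shift)).exp()
    return e / e.sum(axis=1, keepdims=True)


def log_softmax_channels(logits: Tensor) -> Tensor:
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - Tensor(shift)
    return z - z.exp().sum(axis=1, keepdims=True).log()
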