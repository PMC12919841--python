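"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains and differentiates small convolutional networks on CPU;
this module provides the tensor type those networks are built from.  It is a
deliberately small engine: dense float arrays, define-by-run graphs, and the
handful of operations the attention blocks and backbones need (elementwise
arithmetic, matmul, reductions, 2-D convolution with stride/dilation/groups,
max pooling, and a fused softmax cross-entropy).

Gradients follow the usual conventions: broadcasting in the forward pass is
undone by summation in the backward pass; ``max`` routes the gradient to the
(first-tied) maximal entries; convolutions accumulate input gradients with a
per-tap scatter, which is exact for any stride/dilation combination.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "maxpool2d", "cross_entropy", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference / metrics)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            # broadcast-expand scalar/row gradients up to the data's shape
            self.grad = g if g.shape == self.data.shape else \
                np.broadcast_to(g, self.data.shape).copy()
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            full = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == full)
            gk = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            # ties share the incoming gradient equally
            counts = mask.sum(axis=axis, keepdims=True)
            self._accum(mask * (gk / counts))

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling primitives (NCHW layout)
# ---------------------------------------------------------------------------

def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def _pad_nchw(x, ph, pw, value=0.0):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=value)


def _conv_out_size(size, k, s, p, d):
    keff = (k - 1) * d + 1
    return (size + 2 * p - keff) // s + 1


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, dilation=1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW.  weight: (Cout, Cin//groups, kh, kw).

    Supports groups=1 (dense, im2col + BLAS) and depthwise
    (groups == Cin == Cout, per-tap accumulation).
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    N, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    if groups == 1 and Cin_g != C:
        raise ValueError(f"conv2d: weight expects {Cin_g} input channels, got {C}")
    Ho = _conv_out_size(H, kh, sh, ph, dh)
    Wo = _conv_out_size(W, kw, sw, pw, dw)
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel does not fit the padded input")
    xp = _pad_nchw(x.data, ph, pw)

    if groups == 1:
        view = sliding_window_view(xp, ((kh - 1) * dh + 1, (kw - 1) * dw + 1), axis=(2, 3))
        patches = view[:, :, ::sh, ::sw, ::dh, ::dw]          # (N,C,Ho,Wo,kh,kw)
        cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw)
        wmat = weight.data.reshape(Cout, -1)
        out_data = (cols @ wmat.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    elif groups == C and Cout == C and Cin_g == 1:
        out_data = np.zeros((N, C, Ho, Wo), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i * dh: i * dh + (Ho - 1) * sh + 1: sh,
                        j * dw: j * dw + (Wo - 1) * sw + 1: sw]
                out_data += xs * weight.data[:, 0, i, j][None, :, None, None]
        cols = None
    else:
        raise NotImplementedError("conv2d supports groups=1 or depthwise only")

    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        if not g.flags.c_contiguous:
            g = np.ascontiguousarray(g)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            if weight.requires_grad:
                gcols = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
                weight._accum((gcols.T @ cols).reshape(weight.data.shape))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        wtap = weight.data[:, :, i, j]              # (Cout, C)
                        tmp = np.tensordot(g, wtap, axes=([1], [0]))  # (N,Ho,Wo,C)
                        dxp[:, :, i * dh: i * dh + (Ho - 1) * sh + 1: sh,
                            j * dw: j * dw + (Wo - 1) * sw + 1: sw] += tmp.transpose(0, 3, 1, 2)
                x._accum(dxp[:, :, ph: ph + H, pw: pw + W])
        else:
            if weight.requires_grad:
                dwd = np.zeros_like(weight.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = xp[:, :, i * dh: i * dh + (Ho - 1) * sh + 1: sh,
                                j * dw: j * dw + (Wo - 1) * sw + 1: sw]
                        dwd[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                weight._accum(dwd)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i * dh: i * dh + (Ho - 1) * sh + 1: sh,
                            j * dw: j * dw + (Wo - 1) * sw + 1: sw] += (
                            g * weight.data[:, 0, i, j][None, :, None, None])
                x._accum(dxp[:, :, ph: ph + H, pw: pw + W])

    out = Tensor._make(out_data, parents, backward)
    if not out.requires_grad:
        cols = None  # free im2col buffer when no backward pass will use it
    return out


def maxpool2d(x: Tensor, kernel=2, stride=None, padding=0) -> Tensor:
    """Max pooling, NCHW; padded entries never win (padded with -inf)."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    xp = _pad_nchw(x.data, ph, pw, value=-np.inf)
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    flat = view.reshape(N, C, Ho, Wo, kh * kw)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        n, c, oh, ow = np.indices((N, C, Ho, Wo), sparse=False)
        hsrc = oh * sh - ph + idx // kw
        wsrc = ow * sw - pw + idx % kw
        dx = np.zeros_like(x.data)
        np.add.at(dx, (n, c, hsrc, wsrc), g)
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def batch_norm2d(x: Tensor, weight: Tensor, bias: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Fused batch normalization over (N, H, W) per channel.

    In training mode the batch statistics are used and the running estimates
    are updated in place (unbiased variance, exponential momentum); in eval
    mode the running estimates are constants.
    """
    C = x.data.shape[1]
    gamma = weight.data.reshape(1, C, 1, 1)
    beta = bias.data.reshape(1, C, 1, 1)
    if training:
        axes = (0, 2, 3)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes, keepdims=True)
        xc = x.data - mu
        var = np.mean(xc * xc, axis=axes, keepdims=True)
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = xc * invstd
        out_data = gamma * xhat + beta
        unbias = m / max(m - 1, 1)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu.reshape(C).astype(running_mean.dtype)
        running_var *= (1.0 - momentum)
        running_var += momentum * (unbias * var.reshape(C)).astype(running_var.dtype)

        def backward(g):
            if weight.requires_grad:
                weight._accum((g * xhat).sum(axis=axes))
            if bias.requires_grad:
                bias._accum(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * gamma
                mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
                mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
                x._accum(invstd * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat))
    else:
        rinv = (1.0 / np.sqrt(running_var + eps)).reshape(1, C, 1, 1)
        rmean = running_mean.reshape(1, C, 1, 1)
        xhat = (x.data - rmean) * rinv
        out_data = gamma * xhat + beta

        def backward(g):
            if weight.requires_grad:
                weight._accum((g * xhat).sum(axis=(0, 2, 3)))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(g * (gamma * rinv))

    return Tensor._make(out_data, (x, weight, bias), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    losses = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12))
    out_data = np.asarray(losses.mean(), dtype=logits.data.dtype)

    def backward(g):
        if logits.requires_grad:
            dz = probs.copy()
            dz[np.arange(n), labels] -= 1.0
            logits._accum(g * dz / n)

    return Tensor._make(out_data, (logits,), backward)
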