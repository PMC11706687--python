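"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the primitives a convolutional encoder–decoder
segmentation network needs: elementwise arithmetic, reductions, log-softmax,
2-D convolution (stride 1, arbitrary dilation, zero padding), affine-free
batch normalization, 2×2 ceil-mode max pooling, separable bilinear resizing,
channel concatenation and inverted dropout.  Gradients are accumulated on
every node of the graph (not just leaves), which is what gradient-based
attribution methods need.

A module-level ``guided`` flag switches the ReLU backward rule to guided
backpropagation (negative upstream gradients are blocked at each ReLU),
leaving the forward pass untouched.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "guided_relu_mode",
    "relu",
    "log_softmax",
    "conv2d",
    "batch_norm2d",
    "max_pool2x2",
    "resize_bilinear",
    "concat",
    "dropout",
]

# Backward-rule switch for guided backpropagation.
_GUIDED = [False]


@contextlib.contextmanager
def guided_relu_mode():
    """Within this context every ReLU blocks negative upstream gradients."""
    _GUIDED.append(True)
    try:
        yield
    finally:
        _GUIDED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._result(out_data, (self, other), backward)

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant exponent."""
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                if exponent == 0:
                    self._accum(np.zeros_like(self.data))
                else:
                    self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient passes only where x > lo."""
        out_data = np.maximum(self.data, lo)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > lo))

        return Tensor._result(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
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

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._result(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# neural-network primitives
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            if _GUIDED[-1]:
                x._accum(g * mask * (g > 0))
            else:
                x._accum(g * mask)

    return Tensor._result(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        if x.requires_grad:
            softmax = np.exp(out_data)
            x._accum(g - softmax * g.sum(axis=axis, keepdims=True))

    return Tensor._result(out_data, (x,), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, dilation: int = 1) -> Tensor:
    """3×3 (or k×k) convolution, stride 1, zero padding = dilation·(k−1)/2.

    Implemented as a sum of k² shifted channel contractions, which keeps the
    memory footprint flat and maps onto BLAS matmuls.
    """
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out_data = np.zeros((n, cout, h, w), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            oi, oj = ki * dilation, kj * dilation
            patch = xp[:, :, oi : oi + h, oj : oj + w]
            # (cout, cin) x (n, cin, h, w) -> (n, cout, h, w)
            out_data += np.moveaxis(
                np.tensordot(weight.data[:, :, ki, kj], patch, axes=([1], [1])), 0, 1
            )
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        for ki in range(kh):
            for kj in range(kw):
                oi, oj = ki * dilation, kj * dilation
                if weight.requires_grad:
                    patch = xp[:, :, oi : oi + h, oj : oj + w]
                    # (n, cout, h, w) x (n, cin, h, w) -> (cout, cin)
                    gw = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                    if weight.grad is None:
                        weight.grad = np.zeros_like(weight.data)
                    weight.grad[:, :, ki, kj] += gw
                if need_x:
                    # (cin, cout) x (n, cout, h, w) -> (n, cin, h, w)
                    gxp[:, :, oi : oi + h, oj : oj + w] += np.moveaxis(
                        np.tensordot(weight.data[:, :, ki, kj].T, g, axes=([1], [1])),
                        0,
                        1,
                    )
        if need_x:
            if ph or pw:
                x._accum(gxp[:, :, ph : ph + h, pw : pw + w])
            else:
                x._accum(gxp)

    return Tensor._result(out_data, parents, backward)


def batch_norm2d(
    x: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Affine-free batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays owned by the module and
    updated in place during training (exponential moving average with
    unbiased batch variance, matching the common convention).
    """
    if training:
        axes = (0, 2, 3)
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        count = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * (v * count / max(count - 1, 1))
        inv = 1.0 / np.sqrt(v + eps)
        xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]

        def backward(g):
            if not x.requires_grad:
                return
            nhw = count
            sum_g = g.sum(axis=axes)
            sum_gx = (g * xhat).sum(axis=axes)
            gx = (
                g
                - sum_g[None, :, None, None] / nhw
                - xhat * sum_gx[None, :, None, None] / nhw
            ) * inv[None, :, None, None]
            x._accum(gx.astype(x.data.dtype))

        return Tensor._result(xhat.astype(x.data.dtype), (x,), backward)

    inv = 1.0 / np.sqrt(running_var + eps)
    out_data = (x.data - running_mean[None, :, None, None]) * inv[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            x._accum(g * inv[None, :, None, None])

    return Tensor._result(out_data.astype(x.data.dtype), (x,), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2, ceil mode (odd edges padded with −inf)."""
    n, c, h, w = x.data.shape
    ho, wo = (h + 1) // 2, (w + 1) // 2
    ph, pw = ho * 2 - h, wo * 2 - w
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    blocks = xd.reshape(n, c, ho, 2, wo, 2)
    out_data = blocks.max(axis=(3, 5))
    argmask = blocks == out_data[:, :, :, None, :, None]
    # break ties toward the first max so the gradient is routed once
    flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    first = np.zeros_like(flat)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], True, axis=-1)
    first = first.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def backward(g):
        if not x.requires_grad:
            return
        gx = (first * g[:, :, :, None, :, None]).reshape(n, c, ho * 2, wo * 2)
        x._accum(gx[:, :, :h, :w].astype(x.data.dtype))

    return Tensor._result(out_data.astype(x.data.dtype), (x,), backward)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel convention)."""
    key = (n_in, n_out)
    mat = _RESIZE_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n_out, n_in), dtype=np.float64)
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = src - i0
        mat[np.arange(n_out), i0] += 1 - frac
        mat[np.arange(n_out), i1] += frac
        _RESIZE_CACHE[key] = mat
    return mat


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of an (N, C, H, W) tensor."""
    n, c, h, w = x.data.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return x
    r = _resize_matrix(h, ho).astype(x.data.dtype)
    s = _resize_matrix(w, wo).astype(x.data.dtype)
    out_data = np.einsum("oh,nchw,pw->ncop", r, x.data, s, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("oh,ncop,pw->nchw", r, g, s, optimize=True))

    return Tensor._result(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: keep with probability 1−p, scale kept units by 1/(1−p)."""
    if p <= 0:
        return x
    if p >= 1:
        raise ValueError("dropout probability must be < 1")
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    mask = mask.astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._result(x.data * mask, (x,), backward)
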