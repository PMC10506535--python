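"""Reverse-mode automatic differentiation on NumPy arrays.

A compact define-by-run tape: each :class:`Tensor` wraps an ``ndarray`` and
records, for every differentiable operation, a closure that routes the
upstream gradient to its parents.  The op set is exactly what the image
translation networks in this package need — broadcasting arithmetic,
reductions, activations, 2-D convolution, pooling, nearest upsampling,
padding and channel concatenation — and nothing more.

Gradients are accumulated in ``float`` arrays of the same dtype as the data;
use float64 tensors when validating against finite differences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2x",
    "pad2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar unless ``grad`` given)."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at training time
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
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars in this tensor's dtype so float32 graphs do
        # not silently promote to float64
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.dtype))
        return Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(self.dtype, copy=False))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities ------------------------------------
    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def sqrt(self):
        return self**0.5

    def exp(self):
        # capture the value, not `out`, to keep the graph acyclic
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def sigmoid(self):
        val = expit(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, negative_slope * self.data), _parents=(self,))
        slope_arr = np.where(mask, self.dtype.type(1.0), self.dtype.type(negative_slope))
        out._backward = lambda g: self._accum(g * slope_arr)
        return out

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an NCHW tensor."""
    if pad == 0:
        return x
    out = Tensor(
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))), _parents=(x,)
    )
    out._backward = lambda g: x._accum(g[:, :, pad:-pad, pad:-pad])
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation on NCHW input.

    Implemented as a kh*kw slice-gather into an im2col matrix followed by a
    single matmul; the backward pass mirrors it with slice-scatter adds, so
    no per-pixel Python loops occur in either direction.
    """
    n, c, h, w = x.shape
    c_out, c_in, kh, kw = weight.shape
    if c_in != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {c_in}")
    s, p = int(stride), int(padding)
    hp, wp = h + 2 * p, w + 2 * p
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: spatial size {h}x{w} too small for kernel {kh}x{kw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    cols2 = cols.reshape(n, c * kh * kw, ho * wo)
    wmat = weight.data.reshape(c_out, c * kh * kw)
    out_data = np.matmul(wmat, cols2).reshape(n, c_out, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, c_out, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        gmat = g.reshape(n, c_out, ho * wo)
        if weight.requires_grad:
            gw = np.matmul(gmat, cols2.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat).reshape(n, c, kh, kw, ho, wo)
            dxp = np.zeros((n, c, hp, wp), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
            x._accum(dxp[:, :, p : p + h, p : p + w] if p else dxp)

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling on NCHW input; spatial dims must divide."""
    n, c, h, w = x.shape
    f = int(factor)
    if h % f or w % f:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {f}")
    ho, wo = h // f, w // f
    blocks = x.data.reshape(n, c, ho, f, wo, f)
    out = Tensor(blocks.mean(axis=(3, 5)), _parents=(x,))

    def bw(g):
        g_up = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
        x._accum(g_up)

    out._backward = bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,))

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out
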