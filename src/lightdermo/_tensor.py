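"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the network: a :class:`Tensor` wrapping a
float32 ndarray, a handful of differentiable primitives (elementwise math,
matmul, grouped 2-D convolution, 2x2 max pooling, reductions, channel
indexing/concatenation) and a topological backward pass.  It supports exactly
what the architecture needs — nothing more.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "cross_entropy_logits",
    "gelu",
    "leaky_relu",
    "linear",
    "maxpool2x2",
    "relu",
    "sigmoid",
    "softmax",
    "take_channels",
    "tanh",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)

# global multiply-accumulate counter, enabled by complexity reporting
MAC_COUNTER: list | None = None


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd -------------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate from this node.  ``seed`` defaults to ones."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if seed is None else _as_array(seed).reshape(self.data.shape)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- operators ------------------------------------------------------------
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
        return mul(self, power(_wrap(other), -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    grads_needed = any(isinstance(p, Tensor) and (p.requires_grad or p._parents) for p in parents)
    if requires_grad is None:
        requires_grad = grads_needed
    out.requires_grad = requires_grad
    if requires_grad:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise --------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data**p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.where(mask, a.data, 0.0), (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * np.where(mask, 1.0, slope).astype(np.float32))

    return _node(np.where(mask, a.data, slope * a.data), (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def tanh(a) -> Tensor:
    a = _wrap(a)
    t = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - t * t))

    return _node(t, (a,), backward)


def gelu(a) -> Tensor:
    """Exact GELU, x * Phi(x), with Phi the standard normal CDF."""
    a = _wrap(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))

    def backward(g):
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
        a._accumulate(g * (phi + x * pdf).astype(np.float32))

    return _node(x * phi, (a,), backward)


ACTIVATIONS = {
    "gelu": gelu,
    "relu": relu,
    "leakyrelu": leaky_relu,
    "tanh": tanh,
    "sigmoid": sigmoid,
}


# -- shape / indexing ---------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def take_channels(a, index: np.ndarray) -> Tensor:
    """Select/permute channels (axis 1) of a (B, C, H, W) tensor."""
    a = _wrap(a)
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, (slice(None), index), g)
        a._accumulate(ga)

    return _node(a.data[:, index], (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- reductions ---------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / out_data.size

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate((np.broadcast_to(g, a.data.shape) / n).astype(np.float32))

    return _node(out_data, (a,), backward)


# -- linear algebra -----------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    if MAC_COUNTER is not None:
        MAC_COUNTER[0] += a.data.shape[0] * a.data.shape[1] * b.data.shape[1]
    return _node(a.data @ b.data, (a, b), backward)


def linear(x, w, b=None) -> Tensor:
    """x: (B, Fin), w: (Fin, Fout), b: (Fout,)."""
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


# -- convolution --------------------------------------------------------------

def conv2d(x, w, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: (B, Cin, H, W); w: (Cout, Cin/groups, kh, kw).  Biasless: the network
    always follows convolutions with normalization.
    """
    x, w = _wrap(x), _wrap(w)
    B, Cin, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError(
            f"conv2d: channels ({Cin}->{Cout}) incompatible with groups={groups}"
        )
    s = int(stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"conv2d: kernel {kh}x{kw} stride {s} yields empty output on {H}x{W} input"
        )
    wv = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    wvg = wv.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, Cout // groups, Cg, kh, kw)
    out = np.einsum("bgcijuv,gocuv->bgoij", wvg, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(B, Cout, Ho, Wo), dtype=np.float32)
    if MAC_COUNTER is not None:
        MAC_COUNTER[0] += B * Cout * Ho * Wo * Cg * kh * kw

    def backward(g):
        gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if w.requires_grad or w._parents:
            gw = np.einsum("bgcijuv,bgoij->gocuv", wvg, gg, optimize=True)
            w._accumulate(gw.reshape(Cout, Cg, kh, kw).astype(np.float32))
        if x.requires_grad or x._parents:
            dcols = np.einsum("gocuv,bgoij->bgcijuv", wg, gg, optimize=True)
            dcols = dcols.reshape(B, Cin, Ho, Wo, kh, kw)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + s * Ho : s, v : v + s * Wo : s] += dcols[:, :, :, :, u, v]
            if padding:
                dxp = dxp[:, :, padding : Hp - padding, padding : Wp - padding]
            x._accumulate(dxp.astype(np.float32))

    return _node(out, (x, w), backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling, stride 2; requires even spatial extent."""
    x = _wrap(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2: spatial size {H}x{W} is not even")
    xr = (
        x.data.reshape(B, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H // 2, W // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dxr.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W)
        )
        x._accumulate(dx)

    return _node(np.ascontiguousarray(out), (x,), backward)


# -- losses / heads -----------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (inference head; no gradient)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over a batch, from raw logits."""
    labels = np.asarray(labels, dtype=np.intp)
    p = softmax(logits.data, axis=1)
    B = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None)).mean()

    def backward(g):
        dz = p.copy()
        dz[np.arange(B), labels] -= 1.0
        logits._accumulate((g * dz / B).astype(np.float32))

    return _node(np.float32(nll), (logits,), backward)
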