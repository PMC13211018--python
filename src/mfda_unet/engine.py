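"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides the numerical core the rest of the package is built on:
a :class:`Tensor` with a dynamically recorded computation graph, the handful
of differentiable primitives a convolutional/attention segmentation network
needs (dense products, 2-D convolutions, a valid-count box filter, bilinear
resampling, the usual activations and reductions), a small ``Module``
hierarchy for parameter management, and an AdamW optimizer.

Everything is computed in float64.  That keeps analytic identities (DC
rejection, residual skeletons, checkpoint round-trips) exact to the last bit
at the desk scales this package targets, at a modest speed cost.

Gradients are accumulated by closures attached to each output tensor;
``Tensor.backward`` runs them in reverse topological order.  Only the two
convolution layouts the architecture actually uses are implemented
(dense ``groups=1`` and depth-wise ``groups=C``).
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterable, Iterator

import numpy as np
from scipy.special import erf as _erf

DTYPE = np.float64

_grad_enabled = True

# global RNG used for parameter initialization and stochastic layers
# (DropPath); reseed with manual_seed() for reproducible builds/runs.
_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reseed the engine RNG (parameter init and stochastic-depth draws)."""
    global _rng
    _rng = np.random.default_rng(int(seed) % (2**31))


def get_rng() -> np.random.Generator:
    return _rng


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go
                node._backward = None
                node._parents = ()

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1))

    return Tensor._result(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return Tensor._result(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor._result(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return Tensor._result(s, (a,), backward)


def silu(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accum(g * (s + a.data * s * (1.0 - s)))

    return Tensor._result(out_data, (a,), backward)


def elu(a) -> Tensor:
    a = as_tensor(a)
    neg = np.minimum(a.data, 0.0)
    expm = np.expm1(neg)
    out_data = np.where(a.data > 0, a.data, expm)

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.where(a.data > 0, 1.0, expm + 1.0))

    return Tensor._result(out_data, (a,), backward)


def elu_plus_one(a) -> Tensor:
    """Fused ELU(x) + 1 = x + 1 for x > 0, exp(x) for x <= 0.

    Computing exp(x) directly (instead of (exp(x) - 1) + 1) avoids the
    cancellation that would round the result to 0 for large negative x;
    a denormal floor keeps the output strictly positive for any finite
    input.
    """
    a = as_tensor(a)
    neg = np.exp(np.minimum(a.data, 0.0))
    out_data = np.where(a.data > 0, a.data + 1.0,
                        np.maximum(neg, np.finfo(DTYPE).tiny))

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.where(a.data > 0, 1.0, neg))

    return Tensor._result(out_data, (a,), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    phi = 0.5 * (1.0 + _erf(a.data / _SQRT2))
    out_data = a.data * phi

    def backward(g):
        if a.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
            a._accum(g * (phi + a.data * pdf))

    return Tensor._result(out_data, (a,), backward)


def softplus(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)

    def backward(g):
        if a.requires_grad:
            with np.errstate(over="ignore"):
                s = 1.0 / (1.0 + np.exp(-a.data))
            a._accum(g * s)

    return Tensor._result(out_data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.data.shape[ax]
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return Tensor._result(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tuple(ts), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accum(ga)

    return Tensor._result(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# spatial primitives (B, C, H, W)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation).

    ``w`` has shape (C_out, C_in//groups, k, k).  Only ``groups == 1`` and
    depth-wise ``groups == C_in`` (with C_out == C_in) are supported.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    B, Cin, H, W = xd.shape
    k = wd.shape[-1]
    s, p = int(stride), int(padding)
    depthwise = groups != 1
    if depthwise and not (groups == Cin and wd.shape[0] == Cin and wd.shape[1] == 1):
        raise ValueError("only dense (groups=1) or depth-wise convolutions are supported")
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    if s > 1:
        win = win[:, :, ::s, ::s]
    if depthwise:
        out_data = np.einsum("bchwij,cij->bchw", win, wd[:, 0], optimize=True)
    else:
        out_data = np.einsum("bchwij,ocij->bohw", win, wd, optimize=True)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            if depthwise:
                gw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)[:, None]
            else:
                gw = np.einsum("bchwij,bohw->ocij", win, g, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    if depthwise:
                        t = g * wd[:, 0, i, j][None, :, None, None]
                    else:
                        t = np.einsum("bohw,oc->bchw", g, wd[:, :, i, j],
                                      optimize=True)
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += t
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return Tensor._result(out_data, tuple(parents), backward)


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    ``w`` has shape (C_in, C_out, 2, 2); each input pixel emits a 2x2 block,
    blocks do not overlap.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    B, Cin, H, W = xd.shape
    Cout = wd.shape[1]
    t = np.einsum("bchw,coij->bohiwj", xd, wd, optimize=True)
    out_data = t.reshape(B, Cout, 2 * H, 2 * W)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gr = g.reshape(B, Cout, H, 2, W, 2)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("bchw,bohiwj->coij", xd, gr, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("bohiwj,coij->bchw", gr, wd, optimize=True))

    return Tensor._result(out_data, tuple(parents), backward)


def _box_dev_sum(a: np.ndarray) -> np.ndarray:
    """Sum over the valid 3x3 neighbourhood of (neighbour - centre).

    Formulating the box average as ``x + dev_sum(x)/count`` makes spatially
    constant inputs exact fixed points bit-for-bit, including at borders.
    """
    H, W = a.shape[-2], a.shape[-1]
    s = np.zeros_like(a)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            r0, r1 = max(0, -di), min(H, H - di)
            c0, c1 = max(0, -dj), min(W, W - dj)
            if r0 >= r1 or c0 >= c1:
                continue
            s[..., r0:r1, c0:c1] += (a[..., r0 + di:r1 + di, c0 + dj:c1 + dj]
                                     - a[..., r0:r1, c0:c1])
    return s


def box_count_map(H: int, W: int) -> np.ndarray:
    """Number of in-image pixels in each 3x3 window (border-aware)."""
    ch = np.minimum(np.arange(H), 1) + np.minimum(H - 1 - np.arange(H), 1) + 1
    cw = np.minimum(np.arange(W), 1) + np.minimum(W - 1 - np.arange(W), 1) + 1
    return np.asarray(np.outer(ch, cw), dtype=DTYPE)


def box_filter3(x) -> Tensor:
    """3x3 average pooling, stride 1, averaging only valid (in-image) pixels."""
    x = as_tensor(x)
    H, W = x.data.shape[-2], x.data.shape[-1]
    cnt = box_count_map(H, W)
    out_data = x.data + _box_dev_sum(x.data) / cnt

    def backward(g):
        if x.requires_grad:
            # operator is symmetric: adjoint = same deviation-sum structure
            x._accum(g + _box_dev_sum(g / cnt))

    return Tensor._result(out_data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear resampling matrix (half-pixel-centre convention)."""
    A = np.zeros((n_out, n_in), dtype=DTYPE)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    np.add.at(A, (np.arange(n_out), i0), 1.0 - f)
    np.add.at(A, (np.arange(n_out), i1), f)
    return A


def upsample_bilinear(x, size: tuple[int, int]) -> Tensor:
    x = as_tensor(x)
    H, W = x.data.shape[-2], x.data.shape[-1]
    Ho, Wo = size
    if (Ho, Wo) == (H, W):
        return x
    Ah, Aw = _interp_matrix(Ho, H), _interp_matrix(Wo, W)
    out_data = np.einsum("hp,bcpq,wq->bchw", Ah, x.data, Aw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("hp,bchw,wq->bcpq", Ah, g, Aw, optimize=True))

    return Tensor._result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(d)
        extra = set(d) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(d[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _uniform_param(shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return Tensor(_rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = _uniform_param((in_features, out_features), in_features)
        self.bias = _uniform_param((out_features,), in_features) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        return add(y, self.bias) if self.bias is not None else y

    __call__ = forward


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = kernel_size
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = _uniform_param(
            (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in)
        self.bias = _uniform_param((out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)

    __call__ = forward


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (non-overlapping x2 upsample)."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = _uniform_param((in_channels, out_channels, 2, 2), in_channels * 4)
        self.bias = _uniform_param((out_channels,), in_channels * 4) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)

    __call__ = forward


class LayerNorm(Module):
    """Normalization over the last (channel) axis with affine parameters."""

    def __init__(self, num_features: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = tmean(mul(xc, xc), axis=-1, keepdims=True)
        y = div(xc, power(add(var, self.eps), 0.5))
        return add(mul(y, self.gamma), self.beta)

    __call__ = forward


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of (B, C, H, W) feature maps."""

    def __init__(self, num_features: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((num_features, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((num_features, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=1, keepdims=True)
        xc = x - mu
        var = tmean(mul(xc, xc), axis=1, keepdims=True)
        y = div(xc, power(add(var, self.eps), 0.5))
        return add(mul(y, self.gamma), self.beta)

    __call__ = forward


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial standardization, no affine.

    A variance floor (eps) keeps constant inputs finite: they normalize to
    exactly zero.
    """

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=(2, 3), keepdims=True)
        xc = x - mu
        var = tmean(mul(xc, xc), axis=(2, 3), keepdims=True)
        return div(xc, power(add(var, self.eps), 0.5))

    __call__ = forward


class DropPath(Module):
    """Sample-wise stochastic depth: zero a sample's branch with prob. rate."""

    def __init__(self, rate: float = 0.0):
        super().__init__()
        if not 0.0 <= rate <= 1.0:
            raise ValueError("drop-path rate must be in [0, 1]")
        self.rate = rate

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if self.rate >= 1.0:
            return mul(x, 0.0)
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (_rng.random(shape) < keep).astype(DTYPE) / keep
        return mul(x, mask)

    __call__ = forward


def zero_learned_weights(module: Module) -> None:
    """Zero every Linear/Conv weight and bias, leaving norm affines at their
    identity defaults.  Turns residual blocks into identity maps."""
    for m in module.modules():
        if isinstance(m, (Linear, Conv2d, ConvTranspose2x2)):
            m.weight.data[...] = 0.0
            if m.bias is not None:
                m.bias.data[...] = 0.0


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing: lr(0) = lr_max, lr(total_steps) = lr_min exactly."""
    if total_steps <= 0:
        return lr_min
    t = min(max(step, 0), total_steps)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / total_steps))
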