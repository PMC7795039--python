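"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is a small, self-contained tensor/layer library providing exactly
the operations the network needs: dense layers, N-dimensional strided
convolutions and transposed convolutions, batch normalization, the usual
pointwise nonlinearities, global pooling, and an Adam optimizer.  Gradients
are computed by reverse-mode autodiff over a dynamically recorded graph, so
every architectural variant (attention on/off, reconstruction head on/off,
2D or 3D) differentiates end-to-end without per-layer backward code.

All arithmetic is float64: the networks here are small, and double precision
makes finite-difference gradient verification sharp.

Convolutions are implemented by gather/scatter between the (zero-padded)
input volume and an unfolded patch matrix.  The gather indices and the
adjoint scatter operator (a sparse 0/1 matrix) are built once per geometry
and cached; a transposed convolution is literally the adjoint of the
corresponding strided convolution, which is what guarantees the exact
spatial-doubling property the decoder relies on.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv",
    "ConvTranspose",
    "BatchNorm",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "Sequential",
    "Adam",
    "concat_params",
]

_DTYPE = np.float64


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=_DTYPE)


class Tensor:
    """A numpy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # always copy on first accumulation: ``g`` may alias a child's grad
        if self.grad is None:
            self.grad = np.array(g)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
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
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self._backward = None
        self._parents = ()

    # -- operator sugar ----------------------------------------------------

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
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data**p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - out_data**2))

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient strictly inside the bounds."""
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a, axis: tuple[int, ...], keepdims: bool = False) -> Tensor:
    """Max over axes; gradient is split uniformly among tied maxima."""
    a = _wrap(a)
    out_keep = a.data.max(axis=axis, keepdims=True)
    mask = a.data == out_keep
    counts = mask.sum(axis=axis, keepdims=True)
    out_data = out_keep if keepdims else out_keep.squeeze(axis)

    def backward(g):
        gk = g if keepdims else np.expand_dims(g, axis)
        a._accum(np.broadcast_to(gk / counts, a.data.shape) * mask)

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def take_rows(a, idx: np.ndarray) -> Tensor:
    """Select rows along the first axis (integer index array)."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        a._accum(ga)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution geometry (shared by Conv and ConvTranspose)
# ---------------------------------------------------------------------------


class _ConvPlan:
    """Gather indices and adjoint scatter operator for one conv geometry.

    Maps a padded spatial volume of ``pad_spatial`` cells to an unfolded
    matrix of (out_cells, kernel_cells).  ``scatter`` is the sparse adjoint:
    (out_cells * kernel_cells) x pad_cells with 0/1 entries.
    """

    def __init__(self, spatial: tuple[int, ...], kernel: int, stride: int, pad: int):
        dim = len(spatial)
        self.spatial = spatial
        self.pad = pad
        self.pad_spatial = tuple(s + 2 * pad for s in spatial)
        self.out_spatial = tuple(
            (s + 2 * pad - kernel) // stride + 1 for s in spatial
        )
        pad_cells = int(np.prod(self.pad_spatial))
        # flat index of every (output position, kernel offset) pair
        grids = np.meshgrid(
            *[np.arange(o) * stride for o in self.out_spatial], indexing="ij"
        )
        starts = np.stack([g.ravel() for g in grids], axis=1)  # (L, dim)
        koff = np.meshgrid(*[np.arange(kernel)] * dim, indexing="ij")
        koff = np.stack([k.ravel() for k in koff], axis=1)  # (K, dim)
        pos = starts[:, None, :] + koff[None, :, :]  # (L, K, dim)
        flat = np.zeros(pos.shape[:2], dtype=np.intp)
        for d in range(dim):
            flat = flat * self.pad_spatial[d] + pos[..., d]
        self.idx = flat  # (L, K)
        self.L, self.K = flat.shape
        nk = self.L * self.K
        self.scatter = sparse.csr_matrix(
            (np.ones(nk), (np.arange(nk), flat.ravel())),
            shape=(nk, pad_cells),
        )
        # mask selecting the unpadded interior of the padded flat volume
        if pad:
            interior = np.zeros(self.pad_spatial, dtype=bool)
            interior[(slice(pad, -pad),) * dim] = True
            self.interior = interior.ravel()
        else:
            self.interior = None

    def gather(self, x_flat: np.ndarray) -> np.ndarray:
        """(B, C, pad_cells) -> (B, C, L, K)"""
        return x_flat[:, :, self.idx]

    def scatter_add(self, cols: np.ndarray) -> np.ndarray:
        """(B, C, L, K) -> (B, C, pad_cells) accumulating duplicates."""
        b, c = cols.shape[:2]
        flat = cols.reshape(b * c, self.L * self.K)
        out = flat @ self.scatter
        return np.asarray(out).reshape(b, c, -1)

    def pad_input(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x.reshape(x.shape[0], x.shape[1], -1)
        width = [(0, 0), (0, 0)] + [(self.pad, self.pad)] * len(self.spatial)
        return np.pad(x, width).reshape(x.shape[0], x.shape[1], -1)

    def unpad(self, x_flat: np.ndarray) -> np.ndarray:
        b, c = x_flat.shape[:2]
        if self.interior is not None:
            x_flat = x_flat[:, :, self.interior]
        return x_flat.reshape(b, c, *self.spatial)


_PLAN_CACHE: dict[tuple, _ConvPlan] = {}


def _plan(spatial, kernel, stride, pad) -> _ConvPlan:
    key = (tuple(spatial), kernel, stride, pad)
    if key not in _PLAN_CACHE:
        _PLAN_CACHE[key] = _ConvPlan(tuple(spatial), kernel, stride, pad)
    return _PLAN_CACHE[key]


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int) -> Tensor:
    """N-dim cross-correlation. x: (B, Cin, *S); w: (Cout, Cin, k**dim flat)."""
    B, cin = x.data.shape[:2]
    spatial = x.data.shape[2:]
    cout = w.data.shape[0]
    kernel = round(w.data.shape[2] ** (1.0 / len(spatial)))
    plan = _plan(spatial, kernel, stride, pad)
    xf = plan.pad_input(x.data)  # (B, Cin, P)
    cols = plan.gather(xf)  # (B, Cin, L, K)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(B, plan.L, cin * plan.K)
    wmat = w.data.reshape(cout, cin * plan.K)
    y = cols2 @ wmat.T  # (B, L, Cout)
    if b is not None:
        y = y + b.data
    out_data = y.transpose(0, 2, 1).reshape(B, cout, *plan.out_spatial)

    def backward(g):
        g2 = g.reshape(B, cout, plan.L).transpose(0, 2, 1)  # (B, L, Cout)
        if w.requires_grad or w._parents:
            gw = np.tensordot(g2, cols2, axes=([0, 1], [0, 1]))  # (Cout, Cin*K)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g2.sum(axis=(0, 1)))
        if x.requires_grad or x._parents:
            gcols2 = g2 @ wmat  # (B, L, Cin*K)
            gcols = gcols2.reshape(B, plan.L, cin, plan.K).transpose(0, 2, 1, 3)
            gxf = plan.scatter_add(gcols)
            x._accum(plan.unpad(gxf))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv_transpose_nd(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int, out_spatial: Sequence[int]
) -> Tensor:
    """Adjoint of conv_nd: (B, Cin, *S_small) -> (B, Cout, *out_spatial).

    ``w`` has shape (Cin, Cout, K).  The geometry is the conv that maps
    ``out_spatial`` down to the input's spatial shape; with kernel 3, stride 2,
    padding 1 this doubles every extent exactly (output-side padding 1).
    """
    B, cin = x.data.shape[:2]
    small = x.data.shape[2:]
    cout = w.data.shape[1]
    kernel = round(w.data.shape[2] ** (1.0 / len(small)))
    plan = _plan(out_spatial, kernel, stride, pad)
    if plan.out_spatial != tuple(small):
        raise ValueError(
            f"transposed-conv geometry mismatch: adjoint of {tuple(out_spatial)} "
            f"is {plan.out_spatial}, got input {tuple(small)}"
        )
    x2 = x.data.reshape(B, cin, plan.L).transpose(0, 2, 1)  # (B, L, Cin)
    wmat = w.data.reshape(cin, cout * plan.K)
    t = x2 @ wmat  # (B, L, Cout*K)
    cols = t.reshape(B, plan.L, cout, plan.K).transpose(0, 2, 1, 3)
    yf = plan.scatter_add(cols)  # (B, Cout, P)
    out_data = plan.unpad(yf)
    if b is not None:
        out_data = out_data + b.data.reshape((1, cout) + (1,) * len(small))

    def backward(g):
        gf = plan.pad_input(g)  # (B, Cout, P)
        gcols = plan.gather(gf)  # (B, Cout, L, K)
        gt = gcols.transpose(0, 2, 1, 3).reshape(B, plan.L, cout * plan.K)
        if w.requires_grad or w._parents:
            gw = np.tensordot(x2, gt, axes=([0, 1], [0, 1]))  # (Cin, Cout*K)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        if x.requires_grad or x._parents:
            gx2 = gt @ wmat.T  # (B, L, Cin)
            x._accum(gx2.transpose(0, 2, 1).reshape(x.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect_params(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in self.__dict__.values():
            for m in _collect_modules(v):
                out.extend(m.modules())
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_state("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)}")
        for k, arr in own.items():
            arr[...] = state[k]

    def _collect_state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, Tensor):
                out[key] = v.data  # buffers (running stats)
            elif isinstance(v, Module):
                v._collect_state(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", out)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect_params(v) -> Iterable[Parameter]:
    if isinstance(v, Parameter):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_params(item)


def _collect_modules(v) -> Iterable[Module]:
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_modules(item)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.weight.data.shape[0]:
            raise ValueError(
                f"Linear: got {x.data.shape[-1]} features, expected "
                f"{self.weight.data.shape[0]}"
            )
        return add(matmul(x, self.weight), self.bias)


class Conv(Module):
    """N-dim convolution; dim inferred from the input at call time."""

    def __init__(self, dim: int, c_in: int, c_out: int, kernel: int,
                 stride: int, pad: int, rng: np.random.Generator):
        super().__init__()
        k = kernel**dim
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, k), c_in * k))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.weight.data.shape[1]:
            raise ValueError(
                f"Conv: got {x.data.shape[1]} channels, expected "
                f"{self.weight.data.shape[1]}"
            )
        return conv_nd(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose(Module):
    """Stride-2 kernel-3 transposed convolution that exactly doubles extents."""

    def __init__(self, dim: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        k = 3**dim
        self.weight = Parameter(_kaiming(rng, (c_in, c_out, k), c_in * k))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        out_spatial = tuple(2 * s for s in x.data.shape[2:])
        return conv_transpose_nd(x, self.weight, self.bias, 2, 1, out_spatial)


class BatchNorm(Module):
    """Batch normalization over all axes except the feature axis.

    ``feature_axis=1`` normalizes conv maps per channel; for flat (B, F)
    activations use ``feature_axis=-1``.  Training mode uses batch statistics
    and updates exponential running statistics; eval mode — and training-mode
    batches whose reduction count is 1, where the batch variance is degenerate
    — use the running statistics.
    """

    def __init__(self, n_features: int, feature_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = Tensor(np.zeros(n_features))
        self.running_var = Tensor(np.ones(n_features))
        self.feature_axis = feature_axis
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        ax = self.feature_axis % x.data.ndim
        red = tuple(i for i in range(x.data.ndim) if i != ax)
        count = int(np.prod([x.data.shape[i] for i in red]))
        pshape = tuple(-1 if i == ax else 1 for i in range(x.data.ndim))
        if self.training and count > 1:
            mu = reduce_mean(x, axis=red, keepdims=True)
            var = reduce_mean(power(x - mu, 2.0), axis=red, keepdims=True)
            m = self.momentum
            self.running_mean.data *= 1.0 - m
            self.running_mean.data += m * mu.data.reshape(-1)
            unbiased = count / max(count - 1, 1)
            self.running_var.data *= 1.0 - m
            self.running_var.data += m * var.data.reshape(-1) * unbiased
        else:
            mu = Tensor(self.running_mean.data.reshape(pshape))
            var = Tensor(self.running_var.data.reshape(pshape))
        inv = power(var + self.eps, -0.5)
        xhat = (x - mu) * inv
        return xhat * reshape(self.gamma, pshape) + reshape(self.beta, pshape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return tanh(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer (no weight decay).

    A parameter whose gradient is exactly zero (or absent) is left
    bit-identical: its moment estimates stay zero, so the update is zero.
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if not np.any(g):
                continue
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def concat_params(params: Sequence[Parameter]) -> np.ndarray:
    """Flatten a parameter list into one vector (for change detection)."""
    if not params:
        return np.zeros(0)
    return np.concatenate([p.data.ravel() for p in params])
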