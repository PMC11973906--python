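"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a small tape-based autograd
engine with exactly the operations a convolutional encoder-decoder
segmentation network needs (2-D convolution with stride/dilation/groups,
batch normalization, bilinear resampling, adaptive average pooling,
channel/spatial pooling descriptors, pointwise nonlinearities and the
arithmetic used by the losses).  All data is float32; convolutions are
evaluated as strided-window views contracted with ``tensordot``/``einsum``
so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "batch_norm2d",
    "resize_bilinear",
    "adaptive_avg_pool2d",
    "spatial_mean",
    "spatial_max",
    "channel_mean",
    "channel_max",
    "sigmoid",
    "relu",
    "relu6",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction of derived nodes ------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float32)

        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        grads = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other):
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._node(
            self.data + o.data,
            (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._node(
            self.data * o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.data.shape),
                _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._node(
            self.data / o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.data.shape),
                _unbroadcast(-g * self.data / (o.data * o.data), o.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    # -- reductions & elementwise -----------------------------------------
    def sum(self):
        return Tensor._node(
            np.asarray(self.data.sum()), (self,),
            lambda g: (np.broadcast_to(g, self.data.shape).astype(np.float32),),
        )

    def mean(self):
        n = self.data.size
        return self.sum() / float(n)

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo, hi):
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float32)
        return Tensor._node(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._node(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )


# -- nonlinearities --------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._node(s, (x,), lambda g: (g * s * (1.0 - s),))


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float32)
    return Tensor._node(x.data * mask, (x,), lambda g: (g * mask,))


def relu6(x: Tensor) -> Tensor:
    mask = ((x.data > 0) & (x.data < 6.0)).astype(np.float32)
    return Tensor._node(np.clip(x.data, 0.0, 6.0), (x,), lambda g: (g * mask,))


# -- concatenation ---------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(data, tensors, backward)


# -- convolution -----------------------------------------------------------

def _windows(xp: np.ndarray, k: int, stride: int, dilation: int) -> np.ndarray:
    """Strided view (B, C, Ho, Wo, k, k) of a padded input."""
    eff = (k - 1) * dilation + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, (eff, eff), axis=(2, 3))
    return v[:, :, ::stride, ::stride, ::dilation, ::dilation]


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1, depthwise: bool = False) -> Tensor:
    """2-D cross-correlation.

    ``w`` has shape (Cout, Cin, k, k), or (C, 1, k, k) when ``depthwise``
    (one filter per input channel, Cout == Cin).
    """
    k = w.data.shape[-1]
    eff = (k - 1) * dilation + 1
    xp = _pad(x.data, padding)
    v = _windows(xp, k, stride, dilation)
    if depthwise:
        out = np.einsum("bchwij,cij->bchw", v, w.data[:, 0], optimize=True)
    else:
        out = np.tensordot(v, w.data, axes=((1, 4, 5), (1, 2, 3)))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out = out + b.data[None, :, None, None]

    H, W = x.data.shape[2:]
    p = padding

    def backward(g):
        g = np.ascontiguousarray(g)
        # weight gradient
        if depthwise:
            gw = np.einsum("bchw,bchwij->cij", g, v, optimize=True)[:, None]
        else:
            gw = np.tensordot(g, v, axes=((0, 2, 3), (0, 2, 3)))
        # input gradient: scatter g on the stride-1 grid, correlate with
        # the flipped kernel (a transposed convolution).
        Gh = H + 2 * p - eff + 1
        Gw = W + 2 * p - eff + 1
        canvas = np.zeros((g.shape[0], g.shape[1], Gh, Gw), dtype=np.float32)
        canvas[:, :, ::stride, ::stride] = g
        cp = _pad(canvas, eff - 1)
        v2 = _windows(cp, k, 1, dilation)
        if depthwise:
            gx = np.einsum(
                "bchwij,cij->bchw", v2, w.data[:, 0, ::-1, ::-1], optimize=True
            )
        else:
            wt = np.ascontiguousarray(w.data[:, :, ::-1, ::-1])
            gx = np.tensordot(v2, wt, axes=((1, 4, 5), (0, 2, 3)))
            gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        gx = gx[:, :, p:p + H, p:p + W]
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out, parents, backward)


# -- batch normalization ---------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, *, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * ivar[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gx = (
                gxhat
                - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            ) * ivar[None, :, None, None]
            del n
        else:
            gx = gxhat * ivar[None, :, None, None]
        return gx.astype(np.float32), ggamma, gbeta

    return Tensor._node(out, (x, gamma, beta), backward)


# -- resampling ------------------------------------------------------------

_INTERP_CACHE: dict = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-centre convention."""
    key = ("lin", n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        lo = min(max(i0, 0), n_in - 1)
        hi = min(max(i0 + 1, 0), n_in - 1)
        A[o, lo] += 1.0 - t
        A[o, hi] += t
    _INTERP_CACHE[key] = A
    return A


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D adaptive average-pooling matrix (PyTorch bin convention)."""
    key = ("pool", n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    A = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        lo = (o * n_in) // n_out
        hi = -(-((o + 1) * n_in) // n_out)  # ceil
        A[o, lo:hi] = 1.0 / (hi - lo)
    _INTERP_CACHE[key] = A
    return A


def _separable_resample(x: Tensor, Ah: np.ndarray, Aw: np.ndarray) -> Tensor:
    out = np.einsum("oh,bchw,pw->bcop", Ah, x.data, Aw, optimize=True)

    def backward(g):
        gx = np.einsum("oh,bcop,pw->bchw", Ah, g, Aw, optimize=True)
        return (gx.astype(np.float32),)

    return Tensor._node(out.astype(np.float32), (x,), backward)


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    H, W = x.data.shape[2:]
    if (H, W) == tuple(size):
        return x
    return _separable_resample(x, _interp_matrix(H, size[0]), _interp_matrix(W, size[1]))


def adaptive_avg_pool2d(x: Tensor, size: tuple[int, int]) -> Tensor:
    H, W = x.data.shape[2:]
    return _separable_resample(x, _pool_matrix(H, size[0]), _pool_matrix(W, size[1]))


# -- pooled descriptors (attention) ----------------------------------------

def _mean_axes(x: Tensor, axes: tuple) -> Tensor:
    n = np.prod([x.data.shape[a] for a in axes])
    out = x.data.mean(axis=axes, keepdims=True)

    def backward(g):
        return (np.broadcast_to(g / n, x.data.shape).astype(np.float32),)

    return Tensor._node(out, (x,), backward)


def _max_axes(x: Tensor, axes: tuple) -> Tensor:
    out = x.data.max(axis=axes, keepdims=True)
    mask = (x.data == out).astype(np.float32)
    counts = mask.sum(axis=axes, keepdims=True)

    def backward(g):
        return ((mask / counts * g).astype(np.float32),)

    return Tensor._node(out, (x,), backward)


def spatial_mean(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) average descriptor."""
    return _mean_axes(x, (2, 3))


def spatial_max(x: Tensor) -> Tensor:
    return _max_axes(x, (2, 3))


def channel_mean(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, 1, H, W) average map."""
    return _mean_axes(x, (1,))


def channel_max(x: Tensor) -> Tensor:
    return _max_axes(x, (1,))
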