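"""Reverse-mode automatic differentiation on numpy arrays.

A small dynamic-tape engine: every operation returns a new :class:`Tensor`
holding a closure that routes the upstream gradient to its inputs. Float32
throughout. Gradients accumulate into ``.grad`` (a numpy array) on tensors
created with ``requires_grad=True`` or derived from one.

Only the operations the joint model needs are provided; each backward rule
is checked against finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        src = self

        def bw(g):
            buf = np.zeros_like(src.data)
            np.add.at(buf, idx, g)
            src._accum(buf)

        return _make(data, (src,), bw)

    def _accum(self, g: np.ndarray) -> None:
        if not (self.requires_grad or self._prev):
            return  # plain data leaf: nothing downstream needs this gradient
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape (leaf gradients survive; intermediates free memory)
        for node in topo:
            node._backward = None
            node._prev = ()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, inputs: tuple, backward) -> Tensor:
    """Build an op result; record tape only if grad is flowing."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad or t._prev for t in inputs):
        out.requires_grad = False
        out._prev = tuple(inputs)
        out._backward = backward
        # mark: results that depend on a grad-requiring leaf must keep
        # accumulating so their closure runs
        out.requires_grad = any(t.requires_grad for t in inputs) or any(
            t._prev for t in inputs
        )
    return out


# -- arithmetic -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), bw)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        a._accum(-g)

    return _make(-a.data, (a,), bw)


def sub(a, b) -> Tensor:
    return add(a, neg(as_tensor(b)))


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def bw(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(data, (a, b), bw)


def pow_(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data**exponent

    def bw(g):
        a._accum(g * exponent * a.data ** (exponent - 1))

    return _make(data, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        if a.ndim == 1 and b.ndim == 1:
            a._accum(g * b.data)
            b._accum(g * a.data)
            return
        ga = g @ np.swapaxes(b.data, -1, -2) if b.ndim > 1 else np.outer(g, b.data)
        gb = np.swapaxes(a.data, -1, -2) @ g if a.ndim > 1 else np.outer(a.data, g)
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), bw)


# -- reductions -----------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), bw)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reduce_max(a) -> Tensor:
    """Max over all elements; gradient routes to the first argmax."""
    a = as_tensor(a)
    idx = int(np.argmax(a.data))
    data = a.data.reshape(-1)[idx]

    def bw(g):
        buf = np.zeros_like(a.data).reshape(-1)
        buf[idx] = float(g)
        a._accum(buf.reshape(a.shape))

    return _make(data, (a,), bw)


def reduce_min(a) -> Tensor:
    return neg(reduce_max(neg(as_tensor(a))))


# -- shape ops ------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        a._accum(g.reshape(a.shape))

    return _make(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bw(g):
        a._accum(np.transpose(g, inv))

    return _make(data, (a,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(data, tuple(tensors), bw)


def pad3d(a, pad: int) -> Tensor:
    """Zero-pad the last three axes symmetrically by ``pad``."""
    a = as_tensor(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 3) + [(pad, pad)] * 3
    data = np.pad(a.data, width)
    sl = tuple([slice(None)] * (a.ndim - 3) + [slice(pad, -pad)] * 3)

    def bw(g):
        a._accum(g[sl])

    return _make(data, (a,), bw)


def roll(a, shifts, axes) -> Tensor:
    a = as_tensor(a)
    data = np.roll(a.data, shifts, axis=axes)
    inv = tuple(-s for s in shifts)

    def bw(g):
        a._accum(np.roll(g, inv, axis=axes))

    return _make(data, (a,), bw)


def take_rows(table, idx: np.ndarray) -> Tensor:
    """``table[idx]`` for a 2-D parameter table and integer index array."""
    table = as_tensor(table)
    data = table.data[idx]

    def bw(g):
        buf = np.zeros_like(table.data)
        np.add.at(buf, idx, g)
        table._accum(buf)

    return _make(data, (table,), bw)


# -- nonlinearities -------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def bw(g):
        a._accum(g * mask)

    return _make(data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        a._accum(g * data)

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        a._accum(g / a.data)

    return _make(data, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accum(data * (g - dot))

    return _make(data, (a,), bw)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        a._accum(g * mask)

    return _make(data, (a,), bw)


# -- normalization (fused backward rules) ---------------------------------

def _norm_core(x: np.ndarray, axes: tuple, eps: float):
    mu = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat, inv


def normalize(a, axes: tuple, gamma=None, beta=None, eps: float = 1e-5) -> Tensor:
    """(x - mean)/std over ``axes`` with optional per-channel affine.

    ``gamma``/``beta`` must broadcast against the normalized array. Serves
    both layer norm (channel axis) and instance norm (spatial axes).
    """
    a = as_tensor(a)
    xhat, inv = _norm_core(a.data, axes, eps)
    inputs: list[Tensor] = [a]
    if gamma is not None:
        gamma, beta = as_tensor(gamma), as_tensor(beta)
        data = xhat * gamma.data + beta.data
        inputs += [gamma, beta]
    else:
        data = xhat
    n = np.prod([a.shape[ax] for ax in axes])

    def bw(g):
        if gamma is not None:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            beta._accum(_unbroadcast(g, beta.shape))
            gx = g * gamma.data
        else:
            gx = g
        m1 = gx.mean(axis=axes, keepdims=True)
        m2 = (gx * xhat).mean(axis=axes, keepdims=True)
        a._accum(inv * (gx - m1 - xhat * m2))

    return _make(data, tuple(inputs), bw)


# -- convolution / pooling / interpolation --------------------------------

_EINSUM_PATHS: dict = {}


def _einsum(eq: str, *ops: np.ndarray) -> np.ndarray:
    """einsum with a cached contraction path (avoids per-call planning)."""
    key = (eq, tuple(op.shape for op in ops))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(eq, *ops, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(eq, *ops, optimize=path)

def conv3d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """3-D cross-correlation.

    x: (N, Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    Implemented as a loop over the k^3 kernel offsets, each a channel-mixing
    matmul on a strided view — no im2col memory blow-up on large volumes.
    The non-overlapping case (stride == k, padding 0) takes a reshape path.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    N, Cin, D, H, W = x.shape
    Cout, Cin2, k, _, _ = w.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin2}")

    if stride == k and padding == 0:
        if D % k or H % k or W % k:
            raise ValueError("non-overlapping conv needs divisible extents")
        Do, Ho, Wo = D // k, H // k, W // k
        xr = x.data.reshape(N, Cin, Do, k, Ho, k, Wo, k)
        data = _einsum("ncdahbwe,ocabe->nodhw", xr, w.data)
        if b is not None:
            data = data + b.data[None, :, None, None, None]

        def bw(g):
            w._accum(_einsum("nodhw,ncdahbwe->ocabe", g, xr))
            gx = _einsum("nodhw,ocabe->ncdahbwe", g, w.data)
            x._accum(gx.reshape(x.shape))
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3, 4)))

        return _make(data, tuple(t for t in (x, w, b) if t is not None), bw)

    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(padding, padding)] * 3) if padding else x.data
    Dp, Hp, Wp = xp.shape[2:]
    Do = (Dp - k) // stride + 1
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    out = np.zeros((N, Cout, Do, Ho, Wo), dtype=np.result_type(xp, w.data))
    wm = w.data.reshape(Cout, Cin, -1)
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                view = xp[:, :, a : a + stride * Do : stride,
                          bb : bb + stride * Ho : stride,
                          c : c + stride * Wo : stride]
                kk = a * k * k + bb * k + c
                out += _einsum("oc,ncdhw->nodhw", wm[:, :, kk], view)
    if b is not None:
        out += b.data[None, :, None, None, None]

    def bw(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    sl = (slice(None), slice(None),
                          slice(a, a + stride * Do, stride),
                          slice(bb, bb + stride * Ho, stride),
                          slice(c, c + stride * Wo, stride))
                    view = xp[sl]
                    gw[:, :, a, bb, c] = _einsum("nodhw,ncdhw->oc", g, view)
                    gxp[sl] += _einsum("nodhw,oc->ncdhw", g, w.data[:, :, a, bb, c])
        w._accum(gw)
        if padding:
            x._accum(gxp[:, :, padding:-padding, padding:-padding, padding:-padding])
        else:
            x._accum(gxp)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    return _make(out, tuple(t for t in (x, w, b) if t is not None), bw)


def avg_pool3d(x, k: int = 2) -> Tensor:
    """Non-overlapping average pooling (kernel = stride = k)."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    if D % k or H % k or W % k:
        raise ValueError("pooling needs divisible extents")
    xr = x.data.reshape(N, C, D // k, k, H // k, k, W // k, k)
    data = xr.mean(axis=(3, 5, 7))
    scale = 1.0 / k**3

    def bw(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None, :, None] * scale,
            (N, C, D // k, k, H // k, k, W // k, k),
        )
        x._accum(gx.reshape(x.shape).copy())

    return _make(data, (x,), bw)


def interp_matrix(n_in: int, n_out: int, mode: str = "linear") -> np.ndarray:
    """1-D resampling matrix (n_out, n_in), half-pixel-centre convention."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        if mode == "nearest":
            j = int(np.clip(np.floor((i + 0.5) * scale), 0, n_in - 1))
            M[i, j] = 1.0
        else:
            src = min(max(src, 0.0), n_in - 1.0)
            j0 = int(np.floor(src))
            j1 = min(j0 + 1, n_in - 1)
            t = src - j0
            M[i, j0] += 1.0 - t
            if j1 != j0:
                M[i, j1] += t
    return M


def axis_apply(a, M: np.ndarray, axis: int) -> Tensor:
    """Apply matrix M (n_out, n_in) along ``axis``."""
    a = as_tensor(a)
    data = np.moveaxis(np.tensordot(M, a.data, axes=([1], [axis])), 0, axis)

    def bw(g):
        a._accum(np.moveaxis(np.tensordot(M.T, g, axes=([1], [axis])), 0, axis))

    return _make(data, (a,), bw)


def resize3d(x, target: tuple, mode: str = "linear") -> Tensor:
    """Resample the last three axes of (N, C, D, H, W) to ``target``."""
    x = as_tensor(x)
    out = x
    for ax, (n_in, n_out) in enumerate(zip(x.shape[2:], target)):
        if n_in == n_out:
            continue
        out = axis_apply(out, interp_matrix(n_in, n_out, mode), ax + 2)
    return out
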