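"""Layer abstractions over the autodiff engine.

Parameters are ``Tensor``s with ``requires_grad=True``; modules discover
them recursively, so optimizers and checkpoints see one flat named dict.
All initializers draw from an explicit ``numpy.random.Generator`` — no
global RNG state anywhere in the package.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        self.stride, self.padding = stride, padding
        self.weight = _param(_kaiming(rng, (cout, cin, kernel, kernel, kernel),
                                      cin * kernel**3))
        self.bias = _param(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, bias: bool = True, *,
                 rng: np.random.Generator):
        bound = np.sqrt(1.0 / nin)
        self.weight = _param(rng.uniform(-bound, bound, size=(nin, nout)))
        self.bias = _param(np.zeros(nout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = T.add(out, self.bias)
        return out


class LayerNorm(Module):
    """Normalize over the trailing feature axis (token layout ..., C)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return T.normalize(x, axes=(x.ndim - 1,), gamma=self.gamma,
                           beta=self.beta, eps=self.eps)


class VolumeNorm(Module):
    """Layer norm for volumes (N, C, D, H, W): statistics over C and space.

    Used where the model normalizes a whole image or embedding volume; a
    per-channel affine keeps it learnable.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = _param(np.ones((1, channels, 1, 1, 1)))
        self.beta = _param(np.zeros((1, channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return T.normalize(x, axes=(1, 2, 3, 4), gamma=self.gamma,
                           beta=self.beta, eps=self.eps)


class InstanceNorm3d(Module):
    """Per-sample, per-channel spatial normalization (batch-size robust)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = _param(np.ones((1, channels, 1, 1, 1)))
        self.beta = _param(np.zeros((1, channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return T.normalize(x, axes=(2, 3, 4), gamma=self.gamma,
                           beta=self.beta, eps=self.eps)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class ConvBlock(Module):
    """Two (conv3x3x3 -> instance norm -> ReLU) layers."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        self.net = Sequential(
            Conv3d(cin, cout, 3, 1, 1, rng=rng), InstanceNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, 1, 1, rng=rng), InstanceNorm3d(cout), ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class ResBlock(Module):
    """Residual block with 1x1x1 projection shortcut on channel change."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, 1, 1, rng=rng)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, 1, 1, rng=rng)
        self.norm2 = InstanceNorm3d(cout)
        self.proj = Conv3d(cin, cout, 1, rng=rng) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        h = T.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return T.relu(T.add(h, skip))


def _relative_index(window: int) -> np.ndarray:
    """Pairwise relative-offset index table for a cubic window."""
    coords = np.stack(np.meshgrid(*([np.arange(window)] * 3), indexing="ij"),
                      axis=-1).reshape(-1, 3)
    rel = coords[:, None, :] - coords[None, :, :] + (window - 1)
    side = 2 * window - 1
    return (rel[..., 0] * side + rel[..., 1]) * side + rel[..., 2]


class SwinBlock3D(Module):
    """One windowed multi-head self-attention block on a 3-D token grid.

    Pre-norm residual layout: ``x + proj(attn(LN(x)))`` then
    ``x + mlp(LN(x))``. Attention is restricted to non-overlapping cubic
    windows; when ``shift`` > 0 the grid is cyclically rolled by ``shift``
    before partitioning (shifted-window mechanism, implemented without a
    boundary mask, i.e. wrapped neighborhoods may attend to each other).
    Windows larger than the token grid are clipped to the grid.
    """

    def __init__(self, dim: int, grid: int, window: int, shift: int,
                 heads: int = 4, mlp_ratio: int = 4, *,
                 rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        window = min(window, grid)
        if grid % window:
            # fall back to one global window when the grid does not tile
            window = grid
        self.window = window
        self.shift = min(shift, window - 1) if window > 1 else 0
        self.grid = grid
        self.heads = heads
        self.dim = dim
        self.norm1 = LayerNorm(dim)
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.mlp1 = Linear(dim, mlp_ratio * dim, rng=rng)
        self.mlp2 = Linear(mlp_ratio * dim, dim, rng=rng)
        side = 2 * window - 1
        self.rel_bias = _param(np.zeros((side**3, heads)))
        self._rel_idx = _relative_index(window)

    def _attend(self, x: Tensor) -> Tensor:
        # x: (B, n, C) token windows
        B, n, C = x.shape
        h, d = self.heads, self.dim // self.heads
        qkv = self.qkv(x)                                     # (B, n, 3C)
        qkv = T.reshape(qkv, (B, n, 3, h, d))
        qkv = T.transpose(qkv, (2, 0, 3, 1, 4))               # (3, B, h, n, d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = T.mul(T.matmul(q, T.transpose(k, (0, 1, 3, 2))), d**-0.5)
        bias = T.take_rows(self.rel_bias, self._rel_idx)      # (n, n, h)
        scores = T.add(scores, T.transpose(bias, (2, 0, 1)))
        attn = T.softmax(scores, axis=-1)
        out = T.matmul(attn, v)                               # (B, h, n, d)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (B, n, C))
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, G, G, G, C) token grid
        N, G, _, _, C = x.shape
        w = self.window
        nw = G // w
        h = self.norm1(x)
        if self.shift:
            h = T.roll(h, (-self.shift,) * 3, (1, 2, 3))
        h = T.reshape(h, (N, nw, w, nw, w, nw, w, C))
        h = T.transpose(h, (0, 1, 3, 5, 2, 4, 6, 7))
        h = T.reshape(h, (N * nw**3, w**3, C))
        h = self._attend(h)
        h = T.reshape(h, (N, nw, nw, nw, w, w, w, C))
        h = T.transpose(h, (0, 1, 4, 2, 5, 3, 6, 7))
        h = T.reshape(h, (N, G, G, G, C))
        if self.shift:
            h = T.roll(h, (self.shift,) * 3, (1, 2, 3))
        x = T.add(x, h)
        m = self.mlp2(T.relu(self.mlp1(self.norm2(x))))
        return T.add(x, m)
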