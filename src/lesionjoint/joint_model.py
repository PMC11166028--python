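"""The joint lesion-segmentation / disease-classification network.

Three cooperating subnetworks on one shared trunk:

* an information-sharing subnetwork — a dual-branch encoder whose local
  branch is a small conv stack and whose global branch tokenizes the
  volume (patch conv + pooling, /16 grid) and runs two shifted-window
  self-attention layers; the branches are blended per task by a learnable
  2x2 cross-stitch, emitting ``fseg`` and ``fcls`` at half resolution;
* a U-shaped segmentation subnetwork whose decoder feature maps at four
  scales (L/8, L/4, L/2, L) are reduced to one channel, upsampled and
  fused with fixed weights (0.25, 0.25, 0.5, 1) into a sigmoid lesion
  probability map;
* a residual classification subnetwork fed through a Lesion Guidance
  Module (LGM) that gates the classification features with an attention
  map derived from the lesion probability map and concatenates the
  downsampled probability map as an auxiliary channel.

Every spatial size is derived from the config so the full-scale (160^3,
32 channels) and desk-scale (32^3, 8 channels) instantiations share one
code path.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import tensor as T
from .nn.modules import (Conv3d, ConvBlock, Linear, Module, ResBlock,
                         SwinBlock3D, VolumeNorm, _param)
from .nn.tensor import Tensor

LGM_VARIANTS = ("full", "dot_product", "concat", "dot_add", "off")
SHARE_VARIANTS = ("dual", "only_local", "only_global", "off")


@dataclasses.dataclass
class ModelConfig:
    input_size: tuple = (160, 160, 160)
    shared_channels: int = 32
    patch_kernel: int = 8
    patch_stride: int = 8
    pool_kernel: int = 2
    pool_stride: int = 2
    swin_layers: int = 2
    swin_window: int = 5
    swin_heads: int = 4
    swin_mlp_ratio: int = 4
    seg_encoder_blocks: int = 3
    cls_channels: tuple = (64, 128, 256)
    fusion_weights: tuple = (0.25, 0.25, 0.5, 1.0)
    lgm_variant: str = "full"
    share_variant: str = "dual"
    attention_mode: str = "sigmoid"   # voxelwise gates; "softmax" optional
    lgm_stride: int = 2               # stride of the LGM fusion convs
    binarize_threshold: float = 0.5

    def __post_init__(self):
        self.input_size = tuple(int(s) for s in self.input_size)
        if len(set(self.input_size)) != 1:
            raise ValueError("input_size must be cubic (token grid is cubic)")
        factor = self.patch_stride * self.pool_stride
        for s in self.input_size:
            if s % factor or s % 16:
                raise ValueError(
                    f"input edge {s} must be divisible by {factor} and 16 "
                    "(token grid and segmentation ladder)")
        if len(self.fusion_weights) != 4:
            raise ValueError("fusion_weights needs exactly 4 entries")
        if len(self.cls_channels) != 3:
            raise ValueError("cls_channels needs exactly 3 entries")
        if self.seg_encoder_blocks != 3:
            raise ValueError("segmentation path is defined for 3 encoder blocks")
        if self.shared_channels % self.swin_heads:
            raise ValueError("shared_channels must divide by swin_heads")
        if self.lgm_variant not in LGM_VARIANTS:
            raise ValueError(f"unknown lgm_variant {self.lgm_variant!r}")
        if self.share_variant not in SHARE_VARIANTS:
            raise ValueError(f"unknown share_variant {self.share_variant!r}")
        if self.attention_mode not in ("sigmoid", "softmax"):
            raise ValueError("attention_mode must be 'sigmoid' or 'softmax'")
        if self.lgm_stride not in (1, 2):
            raise ValueError("lgm_stride must be 1 or 2")

    @classmethod
    def full(cls, **overrides) -> "ModelConfig":
        """Full-scale configuration (160^3 input, 32 shared channels)."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Reduced configuration that exercises the full graph on a CPU."""
        defaults = dict(input_size=(32, 32, 32), shared_channels=8,
                        cls_channels=(16, 32, 64))
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def token_grid(self) -> int:
        return self.input_size[0] // (self.patch_stride * self.pool_stride)

    @property
    def half_size(self) -> tuple:
        return tuple(s // 2 for s in self.input_size)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("input_size", "cls_channels", "fusion_weights"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class SharedFeatures:
    fseg: Tensor
    fcls: Tensor


@dataclasses.dataclass
class MultiScaleSegMaps:
    """S_i at scales L/8, L/4, L/2 (post-sigmoid) plus the fused full map."""
    maps: list
    fused: Tensor


@dataclasses.dataclass
class LGMState:
    p_down: Tensor | None
    attention: Tensor | None
    d_emph: Tensor | None
    fused: Tensor


@dataclasses.dataclass
class ClsForwardState:
    stage_features: list
    gap_vectors: list
    fc_weights: Tensor
    logits: Tensor
    probs: Tensor


@dataclasses.dataclass
class JointForwardState:
    shared: SharedFeatures
    prob_map: Tensor
    seg_maps: MultiScaleSegMaps
    lgm: LGMState
    cls: ClsForwardState


class DualBranch(Module):
    """Local conv branch + global windowed-attention branch."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        c = cfg.shared_channels
        self.cfg = cfg
        # global branch: patch embedding -> LN -> Swin x2 -> upsample
        self.patch_conv = Conv3d(1, c, cfg.patch_kernel,
                                 stride=cfg.patch_stride, rng=rng)
        self.embed_norm = VolumeNorm(c)
        grid = cfg.token_grid
        shift = cfg.swin_window // 2
        self.swin = [
            SwinBlock3D(c, grid, cfg.swin_window,
                        shift if i % 2 else 0, cfg.swin_heads,
                        cfg.swin_mlp_ratio, rng=rng)
            for i in range(cfg.swin_layers)
        ]
        # local branch: LN -> conv(s2) -> conv -> conv
        self.input_norm = VolumeNorm(1)
        self.local_conv1 = Conv3d(1, c, 3, stride=2, padding=1, rng=rng)
        self.local_conv2 = Conv3d(c, c, 3, stride=1, padding=1, rng=rng)
        self.local_conv3 = Conv3d(c, c, 3, stride=1, padding=1, rng=rng)

    def patch_embed(self, x: Tensor) -> Tensor:
        """Patch conv (k=8, s=8) then 2x average pooling: /16 token volume."""
        e = self.patch_conv(x)
        return T.avg_pool3d(e, self.cfg.pool_kernel)

    def global_branch(self, x: Tensor) -> Tensor:
        e = self.patch_embed(x)
        h = self.embed_norm(e)
        # to token layout (N, G, G, G, C)
        h = T.transpose(h, (0, 2, 3, 4, 1))
        for blk in self.swin:
            h = blk(h)
        h = T.transpose(h, (0, 4, 1, 2, 3))
        return T.resize3d(h, self.cfg.half_size, "linear")

    def local_branch(self, x: Tensor) -> Tensor:
        h = self.input_norm(x)
        h = T.relu(self.local_conv1(h))
        h = T.relu(self.local_conv2(h))
        return self.local_conv3(h)


class CrossStitch(Module):
    """Learnable 2x2 scalar mixing of the two branches, identity-initialized."""

    def __init__(self):
        self.w_seg1 = _param(1.0)
        self.w_seg2 = _param(0.0)
        self.w_cls1 = _param(1.0)
        self.w_cls2 = _param(0.0)

    def forward(self, local: Tensor, global_: Tensor) -> SharedFeatures:
        if local.shape != global_.shape:
            raise ValueError("branch outputs must be conformable")
        fseg = T.add(T.mul(self.w_seg1, local), T.mul(self.w_seg2, global_))
        fcls = T.add(T.mul(self.w_cls1, global_), T.mul(self.w_cls2, local))
        return SharedFeatures(fseg=fseg, fcls=fcls)


class InfoShareNet(Module):
    """Information-sharing subnetwork with its ablation variants."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        self.cfg = cfg
        self.branch = DualBranch(cfg, rng=rng)
        if cfg.share_variant == "dual":
            self.stitch = CrossStitch()
        elif cfg.share_variant == "off":
            # independent extractor per task, each with its own mixer
            self.branch_cls = DualBranch(cfg, rng=rng)
            self.mix_seg = CrossStitch()
            self.mix_cls = CrossStitch()

    # direct access to the component operations
    def patch_embed(self, x: Tensor) -> Tensor:
        return self.branch.patch_embed(x)

    def global_branch(self, x: Tensor) -> Tensor:
        return self.branch.global_branch(x)

    def local_branch(self, x: Tensor) -> Tensor:
        return self.branch.local_branch(x)

    def cross_stitch(self, local: Tensor, global_: Tensor) -> SharedFeatures:
        if self.cfg.share_variant != "dual":
            raise ValueError("cross-stitch only exists in the dual variant")
        return self.stitch(local, global_)

    def forward(self, x: Tensor) -> SharedFeatures:
        variant = self.cfg.share_variant
        if variant == "dual":
            return self.stitch(self.branch.local_branch(x),
                               self.branch.global_branch(x))
        if variant == "only_local":
            f = self.branch.local_branch(x)
            return SharedFeatures(fseg=f, fcls=f)
        if variant == "only_global":
            f = self.branch.global_branch(x)
            return SharedFeatures(fseg=f, fcls=f)
        # "off": two unshared dual extractors, one per head
        seg = self.mix_seg(self.branch.local_branch(x),
                           self.branch.global_branch(x))
        cls = self.mix_cls(self.branch_cls.local_branch(x),
                           self.branch_cls.global_branch(x))
        return SharedFeatures(fseg=seg.fseg, fcls=cls.fcls)


class SegNet(Module):
    """U-shaped segmentation subnetwork with multi-scale fusion."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        c = cfg.shared_channels
        self.cfg = cfg
        self.enc1 = ConvBlock(c, c, rng=rng)
        self.down1 = Conv3d(c, 2 * c, 3, stride=2, padding=1, rng=rng)
        self.enc2 = ConvBlock(2 * c, 2 * c, rng=rng)
        self.down2 = Conv3d(2 * c, 4 * c, 3, stride=2, padding=1, rng=rng)
        self.enc3 = ConvBlock(4 * c, 4 * c, rng=rng)
        self.dec1 = ConvBlock(4 * c + 2 * c, 2 * c, rng=rng)
        self.dec2 = ConvBlock(2 * c + c, c, rng=rng)
        c_out = max(c // 2, 4)
        self.dec3 = ConvBlock(c, c_out, rng=rng)
        self.head1 = Conv3d(4 * c, 1, 1, rng=rng)
        self.head2 = Conv3d(2 * c, 1, 1, rng=rng)
        self.head3 = Conv3d(c, 1, 1, rng=rng)
        self.head4 = Conv3d(c_out, 1, 1, rng=rng)
        # lesion-prior initialization: lesions occupy a small fraction of
        # the brain, so start the fused logit around -2 (p ~ 0.12) instead
        # of 0 (p = 0.5); soft-Dice otherwise spends most of its early
        # gradient budget deflating the background.
        for head in (self.head1, self.head2, self.head3, self.head4):
            head.bias.data[:] = -1.0

    def forward(self, fseg: Tensor):
        cfg = self.cfg
        full = cfg.input_size
        e1 = self.enc1(fseg)                      # L/2
        e2 = self.enc2(self.down1(e1))            # L/4
        e3 = self.enc3(self.down2(e2))            # L/8
        d1_in = T.resize3d(e3, tuple(s // 4 for s in full), "linear")
        d1 = self.dec1(T.concat([d1_in, e2], axis=1))   # L/4
        d2_in = T.resize3d(d1, tuple(s // 2 for s in full), "linear")
        d2 = self.dec2(T.concat([d2_in, e1], axis=1))   # L/2
        d3 = self.dec3(T.resize3d(d2, full, "linear"))  # L
        logits = [self.head1(e3), self.head2(d1), self.head3(d2), self.head4(d3)]
        alphas = cfg.fusion_weights
        fused = None
        for a, lg in zip(alphas, logits):
            up = T.resize3d(lg, full, "nearest")
            term = T.mul(up, float(a))
            fused = term if fused is None else T.add(fused, term)
        prob = T.sigmoid(fused)
        # intermediate sub-full-scale maps, post-sigmoid, native scales
        scale_maps = [T.sigmoid(lg) for lg in logits[:3]]
        return prob, MultiScaleSegMaps(maps=scale_maps, fused=prob)


class LGM(Module):
    """Lesion Guidance Module: inject the probability map into the
    classification stream (attention gating + channel concatenation)."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        c = cfg.shared_channels
        s = cfg.lgm_stride
        self.cfg = cfg
        self.variant = cfg.lgm_variant
        if self.variant == "off":
            return
        self.conv_down = Conv3d(1, 1, 3, stride=2, padding=1, rng=rng)
        self.conv_att = Conv3d(1, 1, 3, stride=2, padding=1, rng=rng)
        if self.variant in ("full", "concat"):
            self.conv_p = Conv3d(1, c, 3, stride=s, padding=1, rng=rng)
            self.conv_d = Conv3d(c, c, 3, stride=s, padding=1, rng=rng)
            self.fuse = Conv3d(2 * c, c, 1, rng=rng)
        elif self.variant == "dot_product":
            self.conv_d = Conv3d(c, c, 3, stride=s, padding=1, rng=rng)

    def forward(self, P: Tensor, D: Tensor) -> LGMState:
        if self.variant == "off":
            return LGMState(None, None, None, fused=D)
        p_down = self.conv_down(P)                       # P' at D's grid
        if self.variant == "dot_add":
            return LGMState(p_down, None, None, fused=T.add(D, p_down))
        if self.variant == "concat":
            fused = self.fuse(T.concat([self.conv_p(p_down), self.conv_d(D)],
                                       axis=1))
            return LGMState(p_down, None, None, fused=fused)
        # attention map from the probability map
        att_logits = self.conv_att(P)
        if self.cfg.attention_mode == "softmax":
            n, c_, d, h, w = att_logits.shape
            flat = T.reshape(att_logits, (n, c_, d * h * w))
            att = T.reshape(T.softmax(flat, axis=-1), (n, c_, d, h, w))
        else:
            att = T.sigmoid(att_logits)
        d_emph = T.mul(att, D)
        if self.variant == "dot_product":
            return LGMState(p_down, att, d_emph, fused=self.conv_d(d_emph))
        fused = self.fuse(T.concat([self.conv_p(p_down), self.conv_d(d_emph)],
                                   axis=1))
        return LGMState(p_down, att, d_emph, fused=fused)


class ClsNet(Module):
    """Three residual stages, per-stage global average pooling, one FC."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        c = cfg.shared_channels
        chans = cfg.cls_channels
        self.stages = []
        prev = c
        for ch in chans:
            self.stages.append(Conv3d(prev, ch, 3, stride=2, padding=1, rng=rng))
            self.stages.append(ResBlock(ch, ch, rng=rng))
            prev = ch
        self.fc = Linear(sum(chans), 2, rng=rng)

    def forward(self, J: Tensor) -> ClsForwardState:
        feats = []
        h = J
        for i in range(0, len(self.stages), 2):
            h = self.stages[i](h)
            h = self.stages[i + 1](h)
            feats.append(h)
        gaps = [T.mean(f, axis=(2, 3, 4)) for f in feats]   # (N, C_i)
        pooled = T.concat(gaps, axis=1)
        logits = self.fc(pooled)
        probs = T.softmax(logits, axis=-1)
        return ClsForwardState(stage_features=feats, gap_vectors=gaps,
                               fc_weights=self.fc.weight, logits=logits,
                               probs=probs)


class JointModel(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.share = InfoShareNet(cfg, rng=rng)
        self.seg = SegNet(cfg, rng=rng)
        self.lgm = LGM(cfg, rng=rng)
        self.cls = ClsNet(cfg, rng=rng)

    def forward(self, x: Tensor) -> JointForwardState:
        if tuple(x.shape[2:]) != self.cfg.input_size:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != {self.cfg.input_size}")
        shared = self.share(x)
        prob, seg_maps = self.seg(shared.fseg)
        lgm_state = self.lgm(prob, shared.fcls)
        cls_state = self.cls(lgm_state.fused)
        return JointForwardState(shared=shared, prob_map=prob,
                                 seg_maps=seg_maps, lgm=lgm_state,
                                 cls=cls_state)

    def predict(self, volume: np.ndarray):
        """Inference on one (D, H, W) volume: probability map, binary mask,
        class probabilities."""
        with T.no_grad():
            state = self.forward(Tensor(volume[None, None]))
        probs = state.prob_map.data[0, 0]
        mask = (probs >= self.cfg.binarize_threshold).astype(np.uint8)
        return probs, mask, state.cls.probs.data[0]

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        np.savez(str(path), __config__=np.frombuffer(
            self.cfg.to_json().encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str | Path) -> "JointModel":
        with np.load(str(path)) as zf:
            cfg = ModelConfig.from_json(bytes(zf["__config__"]).decode())
            model = cls(cfg)
            state = {k: zf[k] for k in zf.files if k != "__config__"}
        model.load_state_dict(state)
        return model
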