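"""Multi-branch encoder: three branches over the input pyramid.

The center branch consumes the raw image I1 (its own 4x patch embedding);
the mid branch consumes the 96-channel H/4 pyramid level through a 1x1
stem; the small branch consumes the 192-channel H/8 level, skipping stage 1
entirely.  All three end at the common width (768 at full scale) and
spatial size H/32, asserted at every forward pass.

``center_branch`` selects which architecture sits at the center: with
``swin`` (default) the side branches are ConvNeXt-based, with ``convnext``
the sides are Swin-based — the swap keeps every shape contract intact.
Single-branch variants (``swin``/``convnext``/``resnet`` alone on I1)
cover the encoder-ablation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .convnext import ConvNeXtBranch, ResNetBranch
from .nn import Module
from .pyramid import MultiScaleInput
from .swin import SwinBranch

__all__ = ["EncoderConfig", "FeaturePyramid", "MultiBranchEncoder"]

_VARIANTS = ("multiscale", "swin_only", "convnext_only", "resnet_only")


@dataclass(frozen=True)
class EncoderConfig:
    stage_channels: tuple = (96, 192, 384, 768)
    swin_depths: tuple = (2, 2, 6, 2)
    conv_depths: tuple = (3, 3, 9, 3)
    swin_heads: tuple = (3, 6, 12, 24)
    window_size: int = 7
    center_branch: str = "swin"           # architecture on I1: swin | convnext
    variant: str = "multiscale"           # or swin_only | convnext_only | resnet_only
    use_grn: bool = True                  # V2-style blocks; False gives V1 layer scale
    micro_scale: int = 1                  # divisor on stage widths for desk-scale runs

    def __post_init__(self):
        if self.center_branch not in ("swin", "convnext"):
            raise ValueError(f"center_branch must be swin or convnext, got {self.center_branch}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        ch = self.channels
        if any(a >= b for a, b in zip(ch, ch[1:])):
            raise ValueError("stage channels must be strictly increasing")
        for c, h in zip(ch, self.swin_heads):
            if c % h:
                raise ValueError(f"stage width {c} not divisible by head count {h}")

    @property
    def channels(self) -> tuple:
        d = self.micro_scale
        return tuple(c // d for c in self.stage_channels)

    @property
    def out_channels(self) -> int:
        return self.channels[-1]


@dataclass
class FeaturePyramid:
    """Per-branch final maps plus per-resolution intermediate maps for skips."""

    f1: Tensor
    f2: Tensor | None
    f3: Tensor | None
    stage_maps: dict = field(default_factory=dict)  # divisor (4/8/16/32) -> [maps]

    @property
    def branch_outputs(self) -> list:
        return [f for f in (self.f1, self.f2, self.f3) if f is not None]

    def skip_channels(self) -> dict:
        return {div: sum(m.shape[1] for m in maps) for div, maps in self.stage_maps.items()}


def _make_branch(arch: str, role: str, cfg: EncoderConfig, rng: np.random.Generator):
    ch = cfg.channels
    if arch == "swin":
        if role == "center":
            return SwinBranch(3, ch, cfg.swin_depths, cfg.swin_heads, cfg.window_size,
                              rng, stem_block=4, first_stage=0)
        if role == "mid":
            return SwinBranch(96, ch, cfg.swin_depths, cfg.swin_heads, cfg.window_size,
                              rng, stem_block=1, first_stage=0)
        return SwinBranch(192, ch, cfg.swin_depths, cfg.swin_heads, cfg.window_size,
                          rng, stem_block=1, first_stage=1)
    if role == "center":
        return ConvNeXtBranch(3, ch, cfg.conv_depths, rng, first_stage=0,
                              patchify=True, use_grn=cfg.use_grn)
    if role == "mid":
        return ConvNeXtBranch(96, ch, cfg.conv_depths, rng, first_stage=0,
                              patchify=False, use_grn=cfg.use_grn)
    return ConvNeXtBranch(192, ch, cfg.conv_depths, rng, first_stage=1,
                          patchify=False, use_grn=cfg.use_grn)


class MultiBranchEncoder(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.enc2 = self.enc3 = None
        if cfg.variant == "multiscale":
            side = "convnext" if cfg.center_branch == "swin" else "swin"
            self.enc1 = _make_branch(cfg.center_branch, "center", cfg, rng)
            self.enc2 = _make_branch(side, "mid", cfg, rng)
            self.enc3 = _make_branch(side, "small", cfg, rng)
        elif cfg.variant == "swin_only":
            self.enc1 = _make_branch("swin", "center", cfg, rng)
        elif cfg.variant == "convnext_only":
            self.enc1 = _make_branch("convnext", "center", cfg, rng)
        else:
            self.enc1 = ResNetBranch(3, cfg.channels, rng)

    def forward(self, pyramid: MultiScaleInput) -> FeaturePyramid:
        maps1 = self.enc1(pyramid.I1)
        stage_maps = {4: [maps1[0]], 8: [maps1[1]], 16: [maps1[2]], 32: [maps1[3]]}
        if self.cfg.variant != "multiscale":
            return FeaturePyramid(f1=maps1[-1], f2=None, f3=None, stage_maps=stage_maps)
        maps2 = self.enc2(pyramid.I2)
        maps3 = self.enc3(pyramid.I3)    # starts at H/8: three maps
        for div, m in zip((4, 8, 16, 32), maps2):
            stage_maps[div].append(m)
        for div, m in zip((8, 16, 32), maps3):
            stage_maps[div].append(m)
        f1, f2, f3 = maps1[-1], maps2[-1], maps3[-1]
        if not (f1.shape == f2.shape == f3.shape):
            raise AssertionError(
                f"branch outputs disagree: {f1.shape} / {f2.shape} / {f3.shape}")
        return FeaturePyramid(f1=f1, f2=f2, f3=f3, stage_maps=stage_maps)

    # convenience named entry points
    def enc1_forward(self, i1):
        return self.enc1(i1)

    def enc2_forward(self, i2):
        if self.enc2 is None:
            raise RuntimeError("this encoder variant has no mid branch")
        return self.enc2(i2)

    def enc3_forward(self, i3):
        if self.enc3 is None:
            raise RuntimeError("this encoder variant has no small branch")
        return self.enc3(i3)
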