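"""ConvNeXt-style convolutional branches and a ResNet-style fallback branch.

The mid- and small-scale encoder branches are ConvNeXt stages whose stems
are adapted to already-patchified inputs: instead of a strided patchify
stem, the first handled stage starts with a 1x1 convolution plus layer
normalisation that preserves spatial size, so the branch can consume a
pyramid level that is already at the right resolution.  Blocks follow the
V2 recipe (7x7 depthwise conv, layer norm, 4x pointwise expansion, GELU,
global response normalisation, pointwise reduction, residual); a flag falls
back to V1-style blocks (learnable layer scale, no GRN).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, maximum
from .nn import Conv1x1, Conv2d, DepthwiseConv2d, LayerNorm, Module, Parameter
from .pyramid import space_to_depth

__all__ = ["ConvNeXtBlock", "ConvNeXtBranch", "ResNetBranch"]


class GRN(Module):
    """Global response normalisation over spatial dimensions (NCHW)."""

    def __init__(self, dim: int):
        self.gamma = Parameter(np.zeros((1, dim, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, dim, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        gx = ((x * x).sum(axis=(2, 3), keepdims=True) + 1e-12) ** 0.5   # N,C,1,1
        nx = gx / (gx.mean(axis=1, keepdims=True) + 1e-6)
        return self.gamma * (x * nx) + self.beta + x


class ConvNeXtBlock(Module):
    def __init__(self, dim: int, rng: np.random.Generator, use_grn: bool = True,
                 mlp_ratio: int = 4):
        self.dwconv = DepthwiseConv2d(dim, 7, rng)
        self.norm = LayerNorm(dim, axis=1)
        self.pw1 = Conv1x1(dim, mlp_ratio * dim, rng)
        self.pw2 = Conv1x1(mlp_ratio * dim, dim, rng)
        self.grn = GRN(mlp_ratio * dim) if use_grn else None
        self.layer_scale = (None if use_grn
                            else Parameter(np.full((1, dim, 1, 1), 1e-6, dtype=np.float32)))

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw1(self.norm(self.dwconv(x))).gelu()
        if self.grn is not None:
            y = self.grn(y)
        y = self.pw2(y)
        if self.layer_scale is not None:
            y = y * self.layer_scale
        return x + y


class Downsample(Module):
    """LayerNorm + 2x2 stride-2 convolution (as space-to-depth + 1x1)."""

    def __init__(self, dim_in: int, dim_out: int, rng: np.random.Generator):
        self.norm = LayerNorm(dim_in, axis=1)
        self.proj = Conv1x1(4 * dim_in, dim_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(space_to_depth(self.norm(x), 2))


class InPlaceStem(Module):
    """1x1 convolution + layer norm; preserves spatial size."""

    def __init__(self, in_channels: int, dim: int, rng: np.random.Generator):
        self.proj = Conv1x1(in_channels, dim, rng)
        self.norm = LayerNorm(dim, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.proj(x))


class PatchifyStem(Module):
    """Standard 4x4 stride-4 patchify stem (space-to-depth + 1x1) + norm."""

    def __init__(self, in_channels: int, dim: int, rng: np.random.Generator):
        self.proj = Conv1x1(16 * in_channels, dim, rng)
        self.norm = LayerNorm(dim, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.proj(space_to_depth(x, 4)))


class ConvNeXtBranch(Module):
    """ConvNeXt stages from ``first_stage`` onward.

    ``first_stage=0`` with ``patchify=True`` is the standard backbone on a
    raw image; ``patchify=False`` replaces the stem with the in-place 1x1
    stem (mid branch); ``first_stage=1`` omits stage 1 entirely and starts
    with the in-place stem at the stage-2 width (small branch).
    """

    def __init__(self, in_channels: int, stage_channels, depths,
                 rng: np.random.Generator, first_stage: int = 0,
                 patchify: bool = False, use_grn: bool = True):
        self.first_stage = first_stage
        dims = list(stage_channels)[first_stage:]
        depths = list(depths)[first_stage:]
        if patchify:
            if first_stage != 0:
                raise ValueError("patchify stem only makes sense for the full branch")
            self.stem = PatchifyStem(in_channels, dims[0], rng)
        else:
            self.stem = InPlaceStem(in_channels, dims[0], rng)
        self.stages = [[ConvNeXtBlock(dim, rng, use_grn) for _ in range(depth)]
                       for dim, depth in zip(dims, depths)]
        self.downs = [Downsample(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.norm = LayerNorm(dims[-1], axis=1)

    def forward(self, x: Tensor) -> list:
        y = self.stem(as_tensor(x))
        maps = []
        for i, blocks in enumerate(self.stages):
            for block in blocks:
                y = block(y)
            maps.append(self.norm(y) if i == len(self.stages) - 1 else y)
            if i < len(self.downs):
                y = self.downs[i](y)
        return maps


def _maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = x.pad(((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = None
    for u in range(kernel):
        for v in range(kernel):
            sl = xp[:, :, u:u + (ho - 1) * stride + 1:stride, v:v + (wo - 1) * stride + 1:stride]
            out = sl if out is None else maximum(out, sl)
    return out


class Bottleneck(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand with identity/projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, stride: int = 1):
        mid = max(out_ch // 4, 8)
        self.conv1 = Conv1x1(in_ch, mid, rng)
        self.conv2 = Conv2d(mid, mid, 3, rng, stride=stride, padding=1)
        self.conv3 = Conv1x1(mid, out_ch, rng)
        self.norm1 = LayerNorm(mid, axis=1)
        self.norm2 = LayerNorm(mid, axis=1)
        self.norm3 = LayerNorm(out_ch, axis=1)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Conv2d(in_ch, out_ch, 1, rng, stride=stride)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y)).relu()
        y = self.norm3(self.conv3(y))
        sc = x if self.shortcut is None else self.shortcut(x)
        return (y + sc).relu()


class ResNetBranch(Module):
    """Residual bottleneck fallback encoder (single-branch ablation axis).

    Stage widths follow the encoder's common channel plan so its maps feed
    the same decoder; depths default to the classic (3, 4, 6, 3).
    """

    def __init__(self, in_channels: int, stage_channels, rng: np.random.Generator,
                 depths=(3, 4, 6, 3)):
        c0 = stage_channels[0]
        self.stem_conv = Conv2d(in_channels, c0, 7, rng, stride=2, padding=3)
        self.stem_norm = LayerNorm(c0, axis=1)
        self.stages = []
        in_ch = c0
        for i, (dim, depth) in enumerate(zip(stage_channels, depths)):
            blocks = []
            for j in range(depth):
                stride = 2 if (j == 0 and i > 0) else 1
                blocks.append(Bottleneck(in_ch, dim, rng, stride=stride))
                in_ch = dim
            self.stages.append(blocks)

    def forward(self, x: Tensor) -> list:
        y = self.stem_norm(self.stem_conv(as_tensor(x))).relu()
        y = _maxpool2d(y)          # H/4
        maps = []
        for blocks in self.stages:
            for block in blocks:
                y = block(y)
            maps.append(y)
        return maps
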