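"""Hierarchical shifted-window attention branch (Swin-style).

Four stages of windowed multi-head self-attention blocks with patch merging
between stages; window attention alternates between unshifted and shifted
(by half a window) blocks, with the standard additive attention mask making
shifted windows respect the original spatial neighbourhoods.  Feature maps
whose side is not a multiple of the window size are zero-padded for
attention and cropped back afterwards — never silently truncated.

The default geometry matches the Tiny variant: depths (2, 2, 6, 2), heads
(3, 6, 12, 24), window 7, stage widths (96, 192, 384, 768).  Stems are
pluggable so the same stage machinery can start from the raw image (4x4
patch embedding) or from an already-patchified pyramid level (1x1
projection), which the branch-swap encoder variants use.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import LayerNorm, Linear, Module, Parameter, softmax, trunc_normal
from .pyramid import space_to_depth

__all__ = ["SwinBranch", "SwinStem", "WindowAttention", "SwinBlock"]


def _relative_index(window: int) -> np.ndarray:
    """Flat (T, T) index into the (2w-1)^2 relative position bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]          # 2, T, T
    rel = rel.transpose(1, 2, 0) + (window - 1)
    return (rel[..., 0] * (2 * window - 1) + rel[..., 1]).astype(np.int64)


def _shift_mask(hp: int, wp: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask (nW, T, T) for shifted windows."""
    img = np.zeros((hp, wp))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = (img.reshape(hp // window, window, wp // window, window)
              .transpose(0, 2, 1, 3)
              .reshape(-1, window * window))
    diff = win[:, None, :] - win[:, :, None]
    return np.where(diff != 0, -100.0, 0.0).astype(np.float32)


class WindowAttention(Module):
    def __init__(self, dim: int, heads: int, window: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.window = dim, heads, window
        self.scale = (dim // heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Parameter(trunc_normal(rng, ((2 * window - 1) ** 2, heads)))
        self._rel_index = _relative_index(window).reshape(-1)

    def forward(self, windows: Tensor, mask: np.ndarray | None) -> Tensor:
        b, t, c = windows.shape
        h = self.heads
        hd = c // h
        qkv = self.qkv(windows).reshape(b, t, 3, h, hd).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose((0, 1, 3, 2))          # b, h, t, t
        bias = self.rel_bias[self._rel_index].reshape(t, t, h).transpose((2, 0, 1))
        attn = attn + bias.reshape(1, h, t, t)
        if mask is not None:
            nw = mask.shape[0]
            attn = (attn.reshape(b // nw, nw, h, t, t)
                    + mask.reshape(1, nw, 1, t, t)).reshape(b, h, t, t)
        attn = softmax(attn, axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """W-MSA / SW-MSA block on NHWC token maps."""

    def __init__(self, dim: int, heads: int, window: int, shifted: bool,
                 rng: np.random.Generator, mlp_ratio: int = 4):
        self.dim, self.window, self.shifted = dim, window, shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        ws = self.window
        shift = ws // 2 if self.shifted and min(h, w) > ws else 0
        y = self.norm1(x)
        pad_h = (-h) % ws
        pad_w = (-w) % ws
        if pad_h or pad_w:
            y = y.pad(((0, 0), (0, pad_h), (0, pad_w), (0, 0)))
        hp, wp = h + pad_h, w + pad_w
        if shift:
            y = y.roll((-shift, -shift), (1, 2))
            mask = _shift_mask(hp, wp, ws, shift)
        else:
            mask = None
        win = (y.reshape(n, hp // ws, ws, wp // ws, ws, c)
                .transpose((0, 1, 3, 2, 4, 5))
                .reshape(n * (hp // ws) * (wp // ws), ws * ws, c))
        win = self.attn(win, mask)
        y = (win.reshape(n, hp // ws, wp // ws, ws, ws, c)
                .transpose((0, 1, 3, 2, 4, 5))
                .reshape(n, hp, wp, c))
        if shift:
            y = y.roll((shift, shift), (1, 2))
        if pad_h or pad_w:
            y = y[:, :h, :w, :]
        x = x + y
        z = self.norm2(x)
        z = self.fc2(self.fc1(z).gelu())
        return x + z


class PatchMerging(Module):
    """2x2 neighbourhood concatenation + linear reduction to double the width."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"patch merging needs even spatial size, got {h}x{w}")
        y = (x.reshape(n, h // 2, 2, w // 2, 2, c)
              .transpose((0, 1, 3, 2, 4, 5))
              .reshape(n, h // 2, w // 2, 4 * c))
        return self.reduction(self.norm(y))


class SwinStem(Module):
    """Patch embedding: block-b space-to-depth followed by a linear projection.

    ``block=4`` on a raw RGB image is the standard 4x4 patch embedding;
    ``block=1`` projects an already-patchified pyramid level in place.
    """

    def __init__(self, in_channels: int, dim: int, block: int, rng: np.random.Generator):
        self.block = block
        self.proj = Linear(in_channels * block * block, dim, rng)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:  # NCHW -> NHWC tokens
        if self.block > 1:
            x = space_to_depth(x, self.block)
        y = x.transpose((0, 2, 3, 1))
        return self.norm(self.proj(y))


class SwinBranch(Module):
    """Stages of Swin blocks; returns NCHW stage maps, coarsest last."""

    def __init__(self, in_channels: int, stage_channels, depths, heads, window: int,
                 rng: np.random.Generator, stem_block: int = 4, first_stage: int = 0):
        self.first_stage = first_stage
        dims = list(stage_channels)[first_stage:]
        depths = list(depths)[first_stage:]
        heads = list(heads)[first_stage:]
        self.stem = SwinStem(in_channels, dims[0], stem_block, rng)
        self.stages = []
        self.merges = []
        for i, (dim, depth, head) in enumerate(zip(dims, depths, heads)):
            blocks = [SwinBlock(dim, head, window, shifted=(j % 2 == 1), rng=rng)
                      for j in range(depth)]
            self.stages.append(blocks)
            if i + 1 < len(dims):
                self.merges.append(PatchMerging(dim, rng))
        self.norm = LayerNorm(dims[-1])

    def forward(self, x: Tensor) -> list:
        y = self.stem(as_tensor(x))
        maps = []
        for i, blocks in enumerate(self.stages):
            for block in blocks:
                y = block(y)
            out = self.norm(y) if i == len(self.stages) - 1 else y
            maps.append(out.transpose((0, 3, 1, 2)))
            if i < len(self.merges):
                y = self.merges[i](y)
        return maps
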