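"""Decoder: transposed-convolution ladder with summed, projected skips.

The fused map at H/32 is upsampled through blocks of 1x1 conv -> transposed
conv -> 1x1 conv, with channel plan [384, 192, 96, 3] at full scale.  After
each of the first three blocks the encoder stage maps at the matching
resolution are concatenated across branches, projected back to the decoder
width with a 1x1 conv, and summed into the stream.  The first three blocks
upsample 2x (3x3 transposed conv, stride 2); the final block covers the
remaining H/4 -> H step with a single 4x4 stride-4 transposed conv, whose
kernel tiles the output exactly — a 3x3 kernel at stride 4 would leave
every fourth row and column without kernel support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concatenate
from .nn import Conv1x1, ConvTranspose2d, Module

__all__ = ["DecoderConfig", "DecoderBlock", "SkipMerge", "Decoder"]


@dataclass(frozen=True)
class DecoderConfig:
    channel_sequence: tuple = (384, 192, 96, 3)

    def __post_init__(self):
        if self.channel_sequence[-1] != 3:
            raise ValueError("the decoded feature map F' must have 3 channels")


class DecoderBlock(Module):
    """1x1 conv -> kxk transposed conv (stride = upscale) -> 1x1 conv."""

    def __init__(self, in_channels: int, out_channels: int, upscale: int,
                 rng: np.random.Generator):
        if upscale not in (2, 4):
            raise ValueError(f"upscale must be 2 or 4, got {upscale}")
        self.upscale = upscale
        self.conv_in = Conv1x1(in_channels, out_channels, rng)
        if upscale == 2:
            self.deconv = ConvTranspose2d(out_channels, out_channels, 3, rng,
                                          stride=2, padding=1, output_padding=1)
        else:
            self.deconv = ConvTranspose2d(out_channels, out_channels, 4, rng, stride=4)
        self.conv_out = Conv1x1(out_channels, out_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        h, w = x.shape[-2:]
        y = self.conv_out(self.deconv(self.conv_in(x)).gelu())
        if y.shape[-2:] != (h * self.upscale, w * self.upscale):
            raise AssertionError(f"decoder block produced {y.shape[-2:]}, "
                                 f"expected {(h * self.upscale, w * self.upscale)}")
        return y


class SkipMerge(Module):
    """out = decoder_map + conv1x1(concat(branch stage maps))."""

    def __init__(self, concat_channels: int, out_channels: int, rng: np.random.Generator):
        self.proj = Conv1x1(concat_channels, out_channels, rng)

    def forward(self, decoder_map: Tensor, stage_maps: list) -> Tensor:
        decoder_map = as_tensor(decoder_map)
        res = decoder_map.shape[-2:]
        for m in stage_maps:
            if m.shape[-2:] != res:
                raise ValueError(f"skip map resolution {m.shape[-2:]} does not match "
                                 f"decoder stream {res}")
        merged = stage_maps[0] if len(stage_maps) == 1 else concatenate(stage_maps, axis=1)
        return decoder_map + self.proj(merged)


class Decoder(Module):
    """Chains blocks at upscales [2, 2, 2, 4]; skips after the first three."""

    def __init__(self, in_channels: int, skip_channels: dict,
                 rng: np.random.Generator, cfg: DecoderConfig | None = None):
        cfg = cfg or DecoderConfig()
        seq = list(cfg.channel_sequence)
        self.cfg = cfg
        ups = [2, 2, 2, 4]
        chans = [in_channels] + seq
        self.blocks = [DecoderBlock(chans[i], chans[i + 1], ups[i], rng) for i in range(4)]
        # skips follow the decoder up the ladder: H/16, H/8, H/4
        self.skip_divisors = (16, 8, 4)
        self.skips = [SkipMerge(skip_channels[d], c, rng)
                      for d, c in zip(self.skip_divisors, seq[:3])]

    def forward(self, fused: Tensor, stage_maps: dict) -> Tensor:
        y = as_tensor(fused)
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i < 3:
                y = self.skips[i](y, stage_maps[self.skip_divisors[i]])
        return y
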