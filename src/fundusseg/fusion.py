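"""Squeeze-and-excitation-style fusion of the three branch outputs.

Each side-branch map is rescaled per channel by a sigmoid gate computed
from its globally pooled descriptor — F_k_bar = sigmoid(conv1x1(GAP(F_k)))
* F_k — and the fused map is the sum F = F1 + F2_bar + F3_bar.  The two
gates have separate parameters; unlike the classic SE block there is no
reduction bottleneck by default (a single 1x1 conv on the C x 1 x 1
descriptor), though one can be enabled.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import Conv1x1, Module, Sequential

__all__ = ["gap", "FeatureFusion"]


def gap(x):
    """Global average pooling over the spatial axes; keeps 1x1 spatial dims."""
    x = as_tensor(x)
    if x.ndim == 3:
        return x.mean(axis=(1, 2), keepdims=True)
    if x.ndim == 4:
        return x.mean(axis=(2, 3), keepdims=True)
    raise ValueError("expected [C, h, w] or [N, C, h, w]")


class _Gate(Module):
    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 0):
        if reduction:
            hidden = max(channels // reduction, 4)
            self.conv = Sequential(Conv1x1(channels, hidden, rng),
                                   _Relu(), Conv1x1(hidden, channels, rng))
        else:
            self.conv = Conv1x1(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = gap(x)
        if pooled.ndim == 3:
            pooled = pooled.reshape(1, *pooled.shape)
            return (self.conv(pooled).sigmoid() * x.reshape(1, *x.shape)).reshape(x.shape)
        return self.conv(pooled).sigmoid() * x


class _Relu(Module):
    def forward(self, x):
        return x.relu()


class FeatureFusion(Module):
    """F = F1 + gate2(F2) + gate3(F3), with per-branch SE-style gates."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 0):
        self.gate2 = _Gate(channels, rng, reduction)
        self.gate3 = _Gate(channels, rng, reduction)

    def gated2(self, f2):
        return self.gate2(as_tensor(f2))

    def gated3(self, f3):
        return self.gate3(as_tensor(f3))

    def forward(self, f1, f2, f3) -> Tensor:
        f1, f2, f3 = as_tensor(f1), as_tensor(f2), as_tensor(f3)
        if not (f1.shape == f2.shape == f3.shape):
            raise ValueError(f"fusion inputs must share a shape, got "
                             f"{f1.shape} / {f2.shape} / {f3.shape}")
        return f1 + self.gate2(f2) + self.gate3(f3)
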