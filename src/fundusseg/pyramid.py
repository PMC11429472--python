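"""Three-scale input pyramid construction.

The network consumes one RGB image at three scales: the image itself (I1),
and two lossless space-to-depth rearrangements that trade spatial resolution
for channels — block 4 giving 48 channels at H/4 (then channel-replicated to
96 to match the mid-branch stem) and block 8 giving 192 channels at H/8.
Patchification, not pooling: the channel counts 48 = 3*4^2 and 192 = 3*8^2
only arise from moving each b x b block into the channel axis, and both
rearrangements are exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["MultiScaleInput", "space_to_depth", "depth_to_space", "replicate_channels",
           "build_pyramid"]


def space_to_depth(x, block: int):
    """Move each ``block x block`` spatial tile into the channel axis.

    Accepts ``[C, H, W]`` or ``[N, C, H, W]`` (ndarray or autodiff tensor);
    the output satisfies ``out[c*b*b + u*b + v, i, j] == x[c, i*b+u, j*b+v]``.
    """
    b = int(block)
    if x.ndim == 3:
        c, h, w = x.shape
        if h % b or w % b:
            raise ValueError(f"spatial size {h}x{w} not divisible by block {b}")
        return (x.reshape(c, h // b, b, w // b, b)
                 .transpose((0, 2, 4, 1, 3))
                 .reshape(c * b * b, h // b, w // b))
    if x.ndim == 4:
        n, c, h, w = x.shape
        if h % b or w % b:
            raise ValueError(f"spatial size {h}x{w} not divisible by block {b}")
        return (x.reshape(n, c, h // b, b, w // b, b)
                 .transpose((0, 1, 3, 5, 2, 4))
                 .reshape(n, c * b * b, h // b, w // b))
    raise ValueError("expected a 3- or 4-dimensional array")


def depth_to_space(x, block: int):
    """Exact inverse of :func:`space_to_depth`."""
    b = int(block)
    if x.ndim == 3:
        cbb, h, w = x.shape
        if cbb % (b * b):
            raise ValueError(f"channel count {cbb} not divisible by block^2 = {b * b}")
        c = cbb // (b * b)
        return (x.reshape(c, b, b, h, w)
                 .transpose((0, 3, 1, 4, 2))
                 .reshape(c, h * b, w * b))
    if x.ndim == 4:
        n, cbb, h, w = x.shape
        if cbb % (b * b):
            raise ValueError(f"channel count {cbb} not divisible by block^2 = {b * b}")
        c = cbb // (b * b)
        return (x.reshape(n, c, b, b, h, w)
                 .transpose((0, 1, 4, 2, 5, 3))
                 .reshape(n, c, h * b, w * b))
    raise ValueError("expected a 3- or 4-dimensional array")


def replicate_channels(x, target: int):
    """Tile channels so that ``out[c] == x[c mod C]``; ``target`` must be a multiple of C."""
    axis = 0 if x.ndim == 3 else 1
    c = x.shape[axis]
    if target % c:
        raise ValueError(f"target channel count {target} is not a multiple of {c}")
    idx = np.arange(target) % c
    if isinstance(x, Tensor):
        return x[idx] if axis == 0 else x[:, idx]
    return np.take(x, idx, axis=axis)


@dataclass
class MultiScaleInput:
    """The three pyramid tensors fed to the encoder branches.

    ``I2_raw`` is the unreplicated block-4 rearrangement kept so that the
    pyramid stays exactly invertible back to the image.
    """

    I1: object  # [3, H, W]  (or batched)
    I2: object  # [96, H/4, W/4]
    I3: object  # [192, H/8, W/8]
    I2_raw: object  # [48, H/4, W/4]


def build_pyramid(image) -> MultiScaleInput:
    """Build I1/I2/I3 from one RGB image (H and W must be divisible by 32)."""
    h, w = image.shape[-2], image.shape[-1]
    if h % 32 or w % 32:
        raise ValueError(f"image size {h}x{w} must be divisible by 32")
    c = image.shape[-3]
    if c != 3:
        raise ValueError(f"expected 3 channels, got {c}")
    i2_raw = space_to_depth(image, 4)
    return MultiScaleInput(
        I1=image,
        I2=replicate_channels(i2_raw, 96),
        I3=space_to_depth(image, 8),
        I2_raw=i2_raw,
    )
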