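"""Segmentation losses: cross-entropy, Dice, and boundary Dice.

The training objective is a weighted sum

    L = lambda1 * L_ce + lambda2 * L_dice + lambda2 * L_boundary_dice
        (+ lambda_cls * L_cls for the auxiliary tumor classifier),

where the boundary term computes the Dice loss only on morphological
boundary rings: ``y' = dilate(y) - y`` and ``p' = dilate(p) - p``.  The ring
is the OUTER boundary — dilation minus original — which is nonnegative for
probabilities in [0, 1]; dilation is a differentiable iterated window
maximum so the loss stays trainable for soft predictions.  The same weight
``lambda2`` is shared by both Dice terms by default; ``lambda3`` overrides
the boundary weight when set.

All functions accept plain ndarrays or autodiff tensors; given ndarrays
they return an autodiff tensor whose ``float()`` is the loss value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, maximum

__all__ = ["LossConfig", "LossBreakdown", "ce_loss", "dice_loss", "soft_dilate",
           "boundary_dice_loss", "classification_loss", "combined_loss"]


@dataclass
class LossConfig:
    lambda1: float = 1.0          # cross-entropy weight
    lambda2: float = 1.0          # Dice weight, shared with boundary Dice
    lambda3: float | None = None  # optional separate boundary-Dice weight
    lambda_cls: float = 1.0       # auxiliary classification weight
    dilation_kernel: int = 3
    dilation_iters: int = 1
    smooth_eps: float = 1e-6

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda_cls) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.dilation_kernel < 3 or self.dilation_kernel % 2 == 0:
            raise ValueError("dilation_kernel must be an odd integer >= 3")
        if self.smooth_eps <= 0:
            raise ValueError("smooth_eps must be positive")

    @property
    def boundary_weight(self) -> float:
        return self.lambda2 if self.lambda3 is None else self.lambda3


@dataclass
class LossBreakdown:
    l_ce: Tensor
    l_dice: Tensor
    l_boundary_dice: Tensor
    l_cls: Tensor
    total: Tensor

    def as_floats(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("l_ce", "l_dice", "l_boundary_dice", "l_cls", "total")}


def _clip01(p: Tensor, eps: float) -> Tensor:
    p = maximum(p, eps)
    return 1.0 - maximum(1.0 - p, eps)


def ce_loss(y, p, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy averaged over pixels (one-channel sigmoid head)."""
    y = np.asarray(y.data if isinstance(y, Tensor) else y)
    p = as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    pc = _clip01(p, eps)
    ll = Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()
    return -ll.mean()


def dice_loss(y, p, smooth_eps: float = 1e-6) -> Tensor:
    """1 - 2|y.p| / (|y| + |p|), smoothed so empty-vs-empty gives 0."""
    y = as_tensor(y)
    p = as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    inter = (y * p).sum()
    denom = y.sum() + p.sum()
    return 1.0 - (2.0 * inter + smooth_eps) / (denom + smooth_eps)


def soft_dilate(x, kernel: int = 3, iters: int = 1):
    """Iterated k x k window maximum (morphological dilation on binary input).

    Operates on the trailing two axes; zero padding at the border.  Returns
    the same kind (ndarray in, ndarray out).
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    was_array = not isinstance(x, Tensor)
    t = as_tensor(x)
    p = kernel // 2
    pw = [(0, 0)] * (t.ndim - 2) + [(p, p), (p, p)]
    h, w = t.shape[-2], t.shape[-1]
    lead = (slice(None),) * (t.ndim - 2)
    for _ in range(iters):
        tp = t.pad(pw)
        out = None
        for u in range(kernel):
            for v in range(kernel):
                sl = tp[lead + (slice(u, u + h), slice(v, v + w))]
                out = sl if out is None else maximum(out, sl)
        t = out
    return t.data if was_array else t


def boundary_dice_loss(y, p, kernel: int = 3, iters: int = 1,
                       smooth_eps: float = 1e-6) -> Tensor:
    """Dice loss restricted to the outer boundary rings of y and p."""
    y = as_tensor(y)
    p = as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    yb = soft_dilate(y, kernel, iters) - y
    pb = soft_dilate(p, kernel, iters) - p
    return dice_loss(yb, pb, smooth_eps)


def classification_loss(class_y, class_p, eps: float = 1e-7) -> Tensor:
    """Cross-entropy on class probabilities; class_y integer labels [N]."""
    class_p = as_tensor(class_p)
    class_y = np.asarray(class_y, dtype=np.int64).reshape(-1)
    n = class_p.shape[0]
    picked = class_p[(np.arange(n), class_y)]
    return -(maximum(picked, eps).log()).mean()


def combined_loss(y, p, class_y, class_p, cfg: LossConfig | None = None) -> LossBreakdown:
    """All loss terms and their weighted total; NaN in any term is a hard error."""
    cfg = cfg or LossConfig()
    terms = {
        "l_ce": ce_loss(y, p),
        "l_dice": dice_loss(y, p, cfg.smooth_eps),
        "l_boundary_dice": boundary_dice_loss(y, p, cfg.dilation_kernel,
                                              cfg.dilation_iters, cfg.smooth_eps),
        "l_cls": classification_loss(class_y, class_p),
    }
    for name, t in terms.items():
        if not np.isfinite(float(t)):
            raise FloatingPointError(f"loss term {name} is not finite")
    total = (cfg.lambda1 * terms["l_ce"]
             + cfg.lambda2 * terms["l_dice"]
             + cfg.boundary_weight * terms["l_boundary_dice"]
             + cfg.lambda_cls * terms["l_cls"])
    return LossBreakdown(total=total, **terms)
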