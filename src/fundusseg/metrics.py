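"""Overlap metrics: per-image IoU and Dice, dataset means and spreads.

Conventions: predictions are binarised at a fixed probability threshold
(default 0.5); a correct empty prediction on an empty reference scores 1.0;
dataset summaries are per-image (macro) means with sample (n-1) standard
deviations, reported as "mean +/- std".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "iou", "dice", "evaluate"]


def _as_bool(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary, found values {uniq[:5]}")
    return arr.astype(bool)


def iou(x, y) -> float:
    """|X intersect Y| / |X union Y|; 1.0 when both masks are empty."""
    xb, yb = _as_bool(x, "x"), _as_bool(y, "y")
    if xb.shape != yb.shape:
        raise ValueError(f"shape mismatch: {xb.shape} vs {yb.shape}")
    union = np.logical_or(xb, yb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(xb, yb).sum() / union)


def dice(x, y) -> float:
    """2 |X intersect Y| / (|X| + |Y|); 1.0 when both masks are empty."""
    xb, yb = _as_bool(x, "x"), _as_bool(y, "y")
    if xb.shape != yb.shape:
        raise ValueError(f"shape mismatch: {xb.shape} vs {yb.shape}")
    denom = xb.sum() + yb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(xb, yb).sum() / denom)


@dataclass
class EvalReport:
    per_image: list = field(default_factory=list)  # (id, IoU, Dice) triples
    miou: float = 0.0
    mdice: float = 0.0
    std_iou: float = 0.0
    std_dice: float = 0.0
    threshold: float = 0.5

    def summary_line(self) -> str:
        return (f"mIoU {self.miou:.4f} ± {self.std_iou:.4f} / "
                f"mDice {self.mdice:.4f} ± {self.std_dice:.4f}")

    def to_dict(self) -> dict:
        return {
            "per_image": [{"id": i, "iou": a, "dice": d} for i, a, d in self.per_image],
            "miou": self.miou, "mdice": self.mdice,
            "std_iou": self.std_iou, "std_dice": self.std_dice,
            "threshold": self.threshold,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.per_image, columns=["id", "iou", "dice"]).to_csv(path, index=False)


def evaluate(predictions: dict, references: dict, threshold: float = 0.5) -> EvalReport:
    """Per-image IoU/Dice for id-aligned probability maps vs binary masks.

    ``predictions`` maps id -> probability map (or already-binary mask);
    ``references`` maps id -> binary mask.
    """
    missing = sorted(set(references) - set(predictions))
    extra = sorted(set(predictions) - set(references))
    if missing or extra:
        raise KeyError(f"id mismatch; missing predictions for {missing[:10]}, "
                       f"unmatched predictions {extra[:10]}")
    if not references:
        raise ValueError("no images to evaluate")
    rows = []
    for img_id in sorted(references):
        pred = np.asarray(predictions[img_id])
        binary = (pred >= threshold).astype(np.uint8)
        ref = np.asarray(references[img_id])
        rows.append((img_id, iou(binary, ref), dice(binary, ref)))
    ious = np.array([r[1] for r in rows])
    dices = np.array([r[2] for r in rows])
    ddof = 1 if len(rows) > 1 else 0
    return EvalReport(
        per_image=rows,
        miou=float(ious.mean()), mdice=float(dices.mean()),
        std_iou=float(ious.std(ddof=ddof)), std_dice=float(dices.std(ddof=ddof)),
        threshold=threshold,
    )
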