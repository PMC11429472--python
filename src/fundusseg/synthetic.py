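"""Synthetic fundus-like images with single tumor lesions.

Real fundus-tumor datasets are small, private, and dominated by two
properties that make segmentation hard: lesion areas spanning more than an
order of magnitude, and irregular lesion boundaries.  This module generates
images that emulate exactly those properties — a dark circular fundus field
with a smooth illumination gradient and a few curvilinear vessel-like
structures, plus one connected, irregular lesion per image — so the whole
segmentation stack can be exercised end to end without any downloads.

The emulated statistics follow a 254-image clinical fundus-tumor cohort:
40.55% benign / 59.45% malignant class balance, and lesion areas between
roughly 1.5% and 27% of the image (the printed pixel bounds of that cohort
at its native 4304 x 4306 resolution), sampled log-uniformly.  Lesions are
star-shaped regions with radius r(theta) = R * (1 + sum_k a_k sin(k theta +
phi_k)), k <= 6, |a_k| <= 0.35 — irregular but guaranteed connected.
Malignant lesions get stronger boundary perturbation and a darker core so
the image-level class is learnable; this is a modelling convenience, not
clinical appearance.

Everything is a pure function of (config, index): identical inputs give
bit-identical images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk, polygon

__all__ = ["SynthConfig", "SampleRecord", "generate_sample", "generate_dataset",
           "summarize_manifest", "read_manifest", "load_sample"]

LABELS = ("benign", "malignant")


@dataclass(frozen=True)
class SynthConfig:
    image_size: int = 448
    n_images: int = 16
    benign_fraction: float = 0.4055
    lesion_area_fraction_range: tuple = (0.015, 0.27)
    vessel_count: int = 6          # upper bound; 2..vessel_count drawn per image
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_fraction_range must satisfy 0 < min < max < 1")
        if not (0.0 <= self.benign_fraction <= 1.0):
            raise ValueError("benign_fraction must be in [0, 1]")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if lo * self.image_size ** 2 < 9:
            raise ValueError(
                f"minimum lesion area fraction {lo} gives fewer than 9 pixels at "
                f"image size {self.image_size}; no connected blob fits")


@dataclass
class SampleRecord:
    image: np.ndarray   # [3, H, W] float32 in [0, 1], quantised to 1/255 steps
    mask: np.ndarray    # [H, W] uint8 in {0, 1}
    label: str          # "benign" | "malignant"
    lesion_area: int    # == mask.sum()
    id: str


def _lesion_mask(rng: np.random.Generator, size: int, target_fraction: float,
                 bounds: tuple, malignant: bool) -> np.ndarray:
    """Rasterise one star-shaped irregular lesion with area fraction in ``bounds``."""
    lo, hi = bounds
    k_orders = np.arange(2, 7)
    amp_scale = 0.30 if malignant else 0.12
    amps = rng.uniform(-amp_scale, amp_scale, size=k_orders.size)
    amps = np.clip(amps, -0.35, 0.35)
    total = np.abs(amps).sum()
    if total > 0.6:  # keep r(theta) > 0.4 R: star-shaped, hence connected
        amps *= 0.6 / total
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k_orders.size)

    target_area = target_fraction * size * size
    # closed-curve area: 0.5 * int r^2 dtheta = pi R^2 (1 + 0.5 sum a_k^2)
    radius = np.sqrt(target_area / (np.pi * (1.0 + 0.5 * np.sum(amps ** 2))))
    r_max = radius * (1.0 + np.abs(amps).sum())
    margin = r_max + 1.0
    if margin < size / 2.0 - 1.0:
        cy = rng.uniform(margin, size - 1 - margin)
        cx = rng.uniform(margin, size - 1 - margin)
    else:
        cy = cx = (size - 1) / 2.0

    theta = np.linspace(0.0, 2.0 * np.pi, max(64, int(8.0 * np.pi * radius)), endpoint=False)
    modulation = 1.0 + sum(a * np.sin(k * theta + ph)
                           for a, k, ph in zip(amps, k_orders, phases))
    scale = 1.0
    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(30):
        r = scale * radius * modulation
        rr, cc = polygon(cy + r * np.sin(theta), cx + r * np.cos(theta), shape=(size, size))
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[rr, cc] = 1
        area = int(mask.sum())
        frac = area / (size * size)
        if area >= 9 and lo <= frac <= hi:
            break
        # rasterisation error off small polygons: rescale toward the target
        if area == 0:
            scale *= 1.4
        else:
            scale *= float(np.sqrt(np.clip(target_fraction / frac, 0.5, 2.0)))
    if mask.sum() < 9 or not (lo <= mask.sum() / size ** 2 <= hi):
        raise RuntimeError("lesion rasterisation failed to hit the configured area range")
    return mask


def _vessels(rng: np.random.Generator, size: int, count_max: int) -> np.ndarray:
    """Boolean map of a few quadratic-curve vessel-like strokes."""
    vessel = np.zeros((size, size), dtype=bool)
    n = int(rng.integers(2, max(count_max, 2) + 1))
    thickness = max(1, size // 160)
    t = np.linspace(0.0, 1.0, 4 * size)
    for _ in range(n):
        p0 = rng.uniform(0.3, 0.7, size=2) * size
        p2 = rng.uniform(0.0, 1.0, size=2) * size
        p1 = (p0 + p2) / 2.0 + rng.uniform(-0.3, 0.3, size=2) * size
        curve = ((1 - t)[:, None] ** 2 * p0 + 2 * (1 - t)[:, None] * t[:, None] * p1
                 + t[:, None] ** 2 * p2)
        ys = np.clip(curve[:, 0].round().astype(int), 0, size - 1)
        xs = np.clip(curve[:, 1].round().astype(int), 0, size - 1)
        vessel[ys, xs] = True
    if thickness > 1:
        from skimage.morphology import dilation, disk as disk_se
        vessel = dilation(vessel, disk_se(thickness - 1))
    return vessel


def generate_sample(cfg: SynthConfig, index: int) -> SampleRecord:
    """Deterministically generate sample ``index`` of the configured dataset."""
    if not (0 <= index < cfg.n_images):
        raise IndexError(f"index {index} outside [0, {cfg.n_images})")
    rng = np.random.default_rng([max(cfg.seed, 0), index])
    size = cfg.image_size

    benign = rng.random() < cfg.benign_fraction
    label = "benign" if benign else "malignant"

    lo, hi = cfg.lesion_area_fraction_range
    # log-uniform, kept slightly interior so rasterisation error stays in range
    target_fraction = float(np.exp(rng.uniform(np.log(lo * 1.08), np.log(hi * 0.92))))
    mask = _lesion_mask(rng, size, target_fraction, (lo, hi), malignant=not benign)

    # background: dark canvas, circular fundus field, smooth illumination
    img = np.full((size, size, 3), 0.04, dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / (0.48 * size)
    field = rr <= 1.0
    base = np.array([0.62, 0.30, 0.12])
    gx, gy = rng.uniform(-0.08, 0.08, size=2)
    illum = 1.0 - 0.35 * rr ** 2 + gx * (xx - cx) / size + gy * (yy - cy) / size
    img[field] = base[None, :] * illum[field, None]

    vessel = _vessels(rng, size, cfg.vessel_count) & field
    img[vessel] = np.array([0.38, 0.10, 0.05])[None, :] * illum[vessel, None]

    # lesion shading: benign pale and uniform, malignant with a darker core
    les = mask.astype(bool)
    if les.any():
        ys, xs = np.nonzero(les)
        lcy, lcx = ys.mean(), xs.mean()
        lrad = max(np.sqrt(les.sum() / np.pi), 1.0)
        dnorm = np.clip(np.sqrt((ys - lcy) ** 2 + (xs - lcx) ** 2) / (1.6 * lrad), 0.0, 1.0)
        if benign:
            inner, outer = np.array([0.82, 0.70, 0.42]), np.array([0.70, 0.52, 0.28])
        else:
            inner, outer = np.array([0.16, 0.08, 0.06]), np.array([0.45, 0.20, 0.10])
        img[ys, xs] = inner[None, :] + dnorm[:, None] * (outer - inner)[None, :]

    img = np.clip(img, 0.0, 1.0)
    img_u8 = np.round(img * 255.0).astype(np.uint8)
    image = (img_u8.astype(np.float32) / 255.0).transpose(2, 0, 1)

    return SampleRecord(
        image=image, mask=mask, label=label,
        lesion_area=int(mask.sum()), id=f"sample_{index:05d}",
    )


def generate_dataset(cfg: SynthConfig, out_dir) -> str:
    """Write PNG image/mask pairs and a manifest CSV; returns the manifest path."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    rows = []
    try:
        for i in range(cfg.n_images):
            rec = generate_sample(cfg, i)
            img_name = f"{rec.id}.png"
            mask_name = f"{rec.id}_mask.png"
            arr = np.round(rec.image.transpose(1, 2, 0) * 255.0).astype(np.uint8)
            img_path = os.path.join(out_dir, img_name)
            Image.fromarray(arr).save(img_path)
            written.append(img_path)
            mask_path = os.path.join(out_dir, mask_name)
            Image.fromarray(rec.mask * 255).save(mask_path)
            written.append(mask_path)
            rows.append({"id": rec.id, "image_path": img_name,
                         "mask_path": mask_name, "label": rec.label})
        manifest = os.path.join(out_dir, "manifest.csv")
        pd.DataFrame(rows, columns=["id", "image_path", "mask_path", "label"]).to_csv(
            manifest, index=False)
    except OSError as err:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise OSError(f"dataset generation failed, partial outputs removed: {err}") from err
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    required = {"id", "image_path", "mask_path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def load_sample(manifest_path, row) -> SampleRecord:
    """Load one manifest row back into arrays (paths relative to the manifest)."""
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    img = np.asarray(Image.open(os.path.join(base, row["image_path"])).convert("RGB"))
    mask = np.asarray(Image.open(os.path.join(base, row["mask_path"])).convert("L"))
    mask = (mask >= 128).astype(np.uint8)
    return SampleRecord(
        image=(img.astype(np.float32) / 255.0).transpose(2, 0, 1),
        mask=mask, label=str(row["label"]),
        lesion_area=int(mask.sum()), id=str(row["id"]),
    )


def summarize_manifest(manifest_path) -> dict:
    """Class counts and percentages (2 decimals), like a dataset summary table."""
    df = read_manifest(manifest_path)
    if len(df) == 0:
        raise ValueError("manifest has no rows")
    for i, label in enumerate(df["label"]):
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r} in manifest row {i}")
    total = len(df)
    out = {}
    for label in LABELS:
        count = int((df["label"] == label).sum())
        out[label] = {"count": count, "percentage": round(100.0 * count / total, 2)}
    return out
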