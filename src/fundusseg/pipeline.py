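"""Training and inference pipeline.

Optimisation follows a plateau schedule: AdamW starting at 2e-4, halving
the learning rate whenever the best epoch loss has not strictly improved
for 20 epochs, stopping when the rate reaches 5e-7 or when 50 consecutive
epochs pass without a rate reduction (both windows configurable).  The
schedule is epoch-level and driven by the training loss.  Prompts are
teacher-forced with the ground-truth class during training; inference uses
the classifier's prediction through the identical code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage import transform as sktransform

from .autograd import no_grad
from .losses import LossConfig, combined_loss
from .metrics import EvalReport, evaluate
from .model import FundusTumorNet, ModelConfig
from .optim import AdamW
from .synthetic import SampleRecord, load_sample, read_manifest

__all__ = ["AugmentConfig", "TrainConfig", "TrainState", "augment",
           "lr_schedule_step", "train", "fit_samples", "predict", "evaluate_cli",
           "split_manifest"]

HISTORY_COLUMNS = ["epoch", "l_ce", "l_dice", "l_boundary_dice", "l_cls", "total", "lr"]


@dataclass(frozen=True)
class AugmentConfig:
    photometric: bool = True       # hue / saturation / brightness jitter
    geometric: bool = True         # translation, zoom, rotation, aspect ratio
    flips: bool = True             # horizontal / vertical flip, 90-degree rotation
    hue_delta: float = 0.03
    sat_range: tuple = (0.8, 1.2)
    val_range: tuple = (0.8, 1.2)
    translate_frac: float = 0.05
    scale_range: tuple = (0.9, 1.1)
    rotate_deg: float = 15.0

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(photometric=False, geometric=False, flips=False)


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 448
    batch_size: int = 12
    lr_init: float = 2e-4
    lr_factor: float = 0.5
    plateau_patience_epochs: int = 20
    lr_min: float = 5e-7
    no_reduction_stop_epochs: int = 50
    weight_decay: float = 0.01
    max_epochs: int = 200
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.plateau_patience_epochs < 1:
            raise ValueError("plateau patience must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


@dataclass
class TrainState:
    epoch: int = 0
    lr: float = 2e-4
    best_loss: float = float("inf")
    epochs_since_improvement: int = 0
    epochs_since_lr_reduction: int = 0
    stop: bool = False
    history: list = field(default_factory=list)


def lr_schedule_step(state: TrainState, epoch_loss: float, cfg: TrainConfig) -> TrainState:
    """Advance the plateau schedule by one epoch; mutates and returns state."""
    if not np.isfinite(epoch_loss):
        raise FloatingPointError(f"epoch loss is not finite at epoch {state.epoch}")
    state.epoch += 1
    state.epochs_since_lr_reduction += 1
    if epoch_loss < state.best_loss:
        state.best_loss = float(epoch_loss)
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement += 1
    if state.epochs_since_improvement >= cfg.plateau_patience_epochs:
        state.lr = max(state.lr * cfg.lr_factor, cfg.lr_min)
        state.epochs_since_improvement = 0
        state.epochs_since_lr_reduction = 0
        if state.lr <= cfg.lr_min:
            state.stop = True
    if state.epochs_since_lr_reduction >= cfg.no_reduction_stop_epochs:
        state.stop = True
    return state


# -- augmentation -------------------------------------------------------------


def _resize_pair(image: np.ndarray, mask: np.ndarray, size: int):
    if image.shape[1:] != (size, size):
        hwc = image.transpose(1, 2, 0)
        hwc = sktransform.resize(hwc, (size, size), order=1, anti_aliasing=True,
                                 preserve_range=True)
        image = hwc.transpose(2, 0, 1).astype(np.float32)
    if mask.shape != (size, size):
        # linear interpolation + threshold preserves lesion area far better
        # than nearest-neighbour subsampling for small irregular masks
        soft = sktransform.resize(mask.astype(float), (size, size), order=1,
                                  preserve_range=True, anti_aliasing=True)
        mask = (soft >= 0.5).astype(np.uint8)
    return image, mask


def augment(sample: SampleRecord, cfg: AugmentConfig, rng: np.random.Generator,
            size: int | None = None) -> SampleRecord:
    """Geometric ops applied identically to image and mask (mask nearest-
    neighbour); photometric ops to the image only; output stays binary."""
    size = size or sample.image.shape[-1]
    image, mask = _resize_pair(sample.image, sample.mask, size)

    if cfg.photometric:
        hsv = skcolor.rgb2hsv(np.clip(image.transpose(1, 2, 0), 0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_delta, cfg.hue_delta)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*cfg.sat_range), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(*cfg.val_range), 0, 1)
        image = skcolor.hsv2rgb(hsv).transpose(2, 0, 1).astype(np.float32)

    if cfg.geometric:
        center = np.array([size / 2.0, size / 2.0])
        tf = (sktransform.AffineTransform(translation=-center)
              + sktransform.AffineTransform(
                  scale=(rng.uniform(*cfg.scale_range), rng.uniform(*cfg.scale_range)),
                  rotation=np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)))
              + sktransform.AffineTransform(
                  translation=center + rng.uniform(-cfg.translate_frac, cfg.translate_frac,
                                                   size=2) * size))
        hwc = image.transpose(1, 2, 0)
        hwc = sktransform.warp(hwc, tf.inverse, order=1, mode="constant", cval=0.0,
                               preserve_range=True)
        image = hwc.transpose(2, 0, 1).astype(np.float32)
        mask = sktransform.warp(mask.astype(float), tf.inverse, order=0,
                                mode="constant", cval=0.0, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)

    if cfg.flips:
        if rng.random() < 0.5:
            image, mask = image[:, :, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            image, mask = image[:, ::-1, :], mask[::-1, :]
        if rng.random() < 0.5:
            image = np.rot90(image, axes=(1, 2))
            mask = np.rot90(mask)

    return SampleRecord(image=np.ascontiguousarray(image),
                        mask=np.ascontiguousarray(mask),
                        label=sample.label, lesion_area=int(mask.sum()), id=sample.id)


# -- training -----------------------------------------------------------------

_LABEL_TO_INT = {"benign": 0, "malignant": 1}


def _labels_to_int(samples) -> np.ndarray:
    return np.array([_LABEL_TO_INT[s.label] for s in samples], dtype=np.int64)


def fit_samples(samples: list, cfg: TrainConfig, out_dir=None, stop_fn=None,
                model: FundusTumorNet | None = None):
    """Train on in-memory samples; returns (model, state).

    ``stop_fn(epoch, model)`` may return True to end training early (used by
    callers that stop on a quality target).  Writes ``history.csv``,
    ``final.ckpt`` and ``best.ckpt`` when ``out_dir`` is given.
    """
    if not samples:
        raise ValueError("no training samples")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = FundusTumorNet(dataclasses.replace(cfg.model, seed=cfg.seed))
    opt = AdamW(model.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)
    state = TrainState(lr=cfg.lr_init)
    best_state = None

    while state.epoch < cfg.max_epochs and not state.stop:
        order = rng.permutation(len(samples))
        epoch_terms = []
        for start in range(0, len(samples), cfg.batch_size):
            batch = [samples[i] for i in order[start:start + cfg.batch_size]]
            batch = [augment(s, cfg.augment, rng, cfg.input_size) for s in batch]
            images = np.stack([s.image for s in batch])
            masks = np.stack([s.mask for s in batch]).astype(np.float32)
            labels = _labels_to_int(batch)
            out = model(images, class_override=labels)   # teacher forcing
            try:
                breakdown = combined_loss(masks, out["mask_prob"], labels,
                                          out["class_probs"], cfg.loss)
            except FloatingPointError as err:
                raise FloatingPointError(f"epoch {state.epoch}: {err}") from err
            opt.zero_grad()
            breakdown.total.backward()
            opt.lr = state.lr
            opt.step()
            epoch_terms.append(breakdown.as_floats())
        means = {k: float(np.mean([t[k] for t in epoch_terms])) for k in epoch_terms[0]}
        row = {"epoch": state.epoch, **{k: means[k] for k in
                                        ("l_ce", "l_dice", "l_boundary_dice", "l_cls", "total")},
               "lr": state.lr}
        state.history.append(row)
        if means["total"] <= state.best_loss and out_dir:
            best_state = model.state_dict()
        lr_schedule_step(state, means["total"], cfg)
        if out_dir:
            pd.DataFrame(state.history, columns=HISTORY_COLUMNS).to_csv(
                os.path.join(out_dir, "history.csv"), index=False)
        if stop_fn is not None and stop_fn(state.epoch, model):
            break

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        model.save(os.path.join(out_dir, "final.ckpt"))
        if best_state is not None:
            current = model.state_dict()
            model.load_state_dict(best_state)
            model.save(os.path.join(out_dir, "best.ckpt"))
            model.load_state_dict(current)
        pd.DataFrame(state.history, columns=HISTORY_COLUMNS).to_csv(
            os.path.join(out_dir, "history.csv"), index=False)
    return model, state


def train(manifest_path, cfg: TrainConfig, out_dir=None, stop_fn=None):
    """Train from a manifest CSV; returns (model, state)."""
    df = read_manifest(manifest_path)
    samples = [load_sample(manifest_path, row) for _, row in df.iterrows()]
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    return fit_samples(samples, cfg, out_dir=out_dir, stop_fn=stop_fn)


def split_manifest(manifest_path, train_fraction: float = 0.8):
    """Deterministic train/test split of manifest rows by id hash."""
    df = read_manifest(manifest_path)
    cut = int(round(train_fraction * 100))

    def bucket(sample_id: str) -> int:
        h = hashlib.md5(str(sample_id).encode("utf-8")).hexdigest()
        return int(h, 16) % 100

    is_train = df["id"].map(lambda i: bucket(i) < cut)
    return df[is_train].reset_index(drop=True), df[~is_train].reset_index(drop=True)


# -- inference ----------------------------------------------------------------


def _prepare_image(image: np.ndarray, size: int):
    """Resize to the model size; reports whether resizing occurred."""
    resized = image.shape[1:] != (size, size)
    if resized:
        hwc = sktransform.resize(image.transpose(1, 2, 0), (size, size), order=1,
                                 anti_aliasing=True, preserve_range=True)
        image = hwc.transpose(2, 0, 1).astype(np.float32)
    return image, resized


def predict(model: FundusTumorNet, images: list, threshold: float = 0.5,
            input_size: int | None = None, force_class=None) -> list:
    """Per-image probability map, binary mask and class label.

    ``force_class`` overrides the classifier-driven prompt (ablation knob).
    Images whose size is incompatible are resized, recorded in metadata.
    """
    size = input_size or images[0].shape[-1]
    if size % 32:
        size = 32 * max(1, round(size / 32))
    results = []
    for image in images:
        prepared, resized = _prepare_image(np.asarray(image, dtype=np.float32), size)
        out = model.predict(prepared[None], threshold=threshold,
                            class_override=None if force_class is None
                            else [int(force_class)])
        if prepared.shape[1:] != image.shape[1:]:
            prob = sktransform.resize(out["mask_prob"][0], image.shape[1:], order=1,
                                      preserve_range=True)
        else:
            prob = out["mask_prob"][0]
        results.append({
            "mask_prob": prob.astype(np.float32),
            "mask": (prob >= threshold).astype(np.uint8),
            "class_index": int(out["class_index"][0]),
            "class_probs": out["class_probs"][0],
            "resized": bool(resized),
        })
    return results


def evaluate_cli(model: FundusTumorNet, manifest_path, threshold: float = 0.5,
                 input_size: int | None = None) -> EvalReport:
    """Predict every manifest image and score against its reference mask."""
    df = read_manifest(manifest_path)
    if len(df) == 0:
        raise ValueError("manifest has no rows")
    predictions, references = {}, {}
    for _, row in df.iterrows():
        sample = load_sample(manifest_path, row)
        res = predict(model, [sample.image], threshold=threshold,
                      input_size=input_size)[0]
        predictions[sample.id] = res["mask_prob"]
        references[sample.id] = sample.mask
    report = evaluate(predictions, references, threshold=threshold)
    return report
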