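"""Scikit-learn style estimator wrapping the full segmentation pipeline.

`FundusTumorSegmenter` is a `BaseEstimator`: hyperparameters are constructor
arguments, `fit(X, y)` trains the network, `predict(X)` returns binary
masks, and fitted state lives in trailing-underscore attributes — so the
model composes with sklearn model selection and pipelines.

Defaults are desk-scale (64-pixel inputs, quarter-width stages, window 4)
so that fitting is feasible on a single CPU; the full-scale geometry is one
parameter set away (``image_size=448, micro_scale=1, window_size=7,
learning_rate=2e-4, batch_size=12``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossConfig
from .metrics import evaluate
from .model import FundusTumorNet, ModelConfig
from .pipeline import AugmentConfig, TrainConfig, fit_samples, predict as _predict
from .synthetic import SampleRecord
from .encoder import EncoderConfig

__all__ = ["FundusTumorSegmenter"]

_INT_TO_LABEL = {0: "benign", 1: "malignant"}


class FundusTumorSegmenter(BaseEstimator):
    """Multiscale prompt-driven fundus tumor segmenter.

    Parameters
    ----------
    image_size : input resolution (divisible by 32); images are resized.
    micro_scale : divisor on the stage widths (1 = full Tiny-scale model).
    window_size : attention window of the Swin branch.
    center_branch : "swin" or "convnext" — the architecture on the raw image.
    variant : "multiscale" or a single-branch ablation
        ("swin_only" / "convnext_only" / "resnet_only").
    learning_rate, batch_size, max_epochs, weight_decay : optimisation.
    lambda_ce, lambda_dice, lambda_boundary, lambda_cls : loss weights
        (lambda_dice is shared with the boundary term unless
        lambda_boundary is set).
    plateau_patience, lr_min, no_reduction_stop : plateau schedule knobs.
    augment : enable the augmentation pipeline during fit.
    threshold : probability cutoff for predicted masks.
    seed : controls init, shuffling and augmentation.
    """

    def __init__(self, image_size: int = 64, micro_scale: int = 4,
                 window_size: int = 4, center_branch: str = "swin",
                 variant: str = "multiscale", learning_rate: float = 1e-3,
                 batch_size: int = 8, max_epochs: int = 100,
                 weight_decay: float = 0.01, lambda_ce: float = 1.0,
                 lambda_dice: float = 1.0, lambda_boundary: float | None = None,
                 lambda_cls: float = 1.0, plateau_patience: int = 20,
                 lr_min: float = 5e-7, no_reduction_stop: int = 50,
                 augment: bool = False, threshold: float = 0.5, seed: int = 0):
        self.image_size = image_size
        self.micro_scale = micro_scale
        self.window_size = window_size
        self.center_branch = center_branch
        self.variant = variant
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.weight_decay = weight_decay
        self.lambda_ce = lambda_ce
        self.lambda_dice = lambda_dice
        self.lambda_boundary = lambda_boundary
        self.lambda_cls = lambda_cls
        self.plateau_patience = plateau_patience
        self.lr_min = lr_min
        self.no_reduction_stop = no_reduction_stop
        self.augment = augment
        self.threshold = threshold
        self.seed = seed

    # -- config assembly ------------------------------------------------------

    def _train_config(self, lambda_cls: float) -> TrainConfig:
        model_cfg = ModelConfig(
            encoder=EncoderConfig(micro_scale=self.micro_scale,
                                  window_size=self.window_size,
                                  center_branch=self.center_branch,
                                  variant=self.variant),
            seed=self.seed,
        )
        return TrainConfig(
            input_size=self.image_size,
            batch_size=self.batch_size,
            lr_init=self.learning_rate,
            plateau_patience_epochs=self.plateau_patience,
            lr_min=self.lr_min,
            no_reduction_stop_epochs=self.no_reduction_stop,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            seed=self.seed,
            augment=(AugmentConfig() if self.augment else AugmentConfig.disabled()),
            loss=LossConfig(lambda1=self.lambda_ce, lambda2=self.lambda_dice,
                            lambda3=self.lambda_boundary, lambda_cls=lambda_cls),
            model=model_cfg,
        )

    @staticmethod
    def _as_samples(X, y, labels) -> list:
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError("X must be [n_samples, 3, H, W]")
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError("y must be [n_samples, H, W] masks aligned with X")
        samples = []
        for i in range(X.shape[0]):
            if labels is None:
                lab = "benign"
            elif isinstance(labels[i], str):
                lab = labels[i]
            else:
                lab = _INT_TO_LABEL[int(labels[i])]
            samples.append(SampleRecord(image=X[i], mask=y[i].astype(np.uint8),
                                        label=lab, lesion_area=int(y[i].sum()),
                                        id=f"x{i:05d}"))
        return samples

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y, labels=None, stop_fn=None):
        """Fit on images X [n, 3, H, W] and binary masks y [n, H, W].

        ``labels``: optional per-image class (0/1 or "benign"/"malignant")
        supervising the classifier and the teacher-forced prompts; without
        labels the auxiliary classification loss is disabled.
        """
        samples = self._as_samples(X, y, labels)
        lambda_cls = self.lambda_cls if labels is not None else 0.0
        cfg = self._train_config(lambda_cls)
        self.model_, self.state_ = fit_samples(samples, cfg, stop_fn=stop_fn)
        self.history_ = self.state_.history
        self.config_ = cfg
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel lesion probability maps [n, H, W]."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        res = _predict(self.model_, list(X), threshold=self.threshold,
                       input_size=self.image_size)
        return np.stack([r["mask_prob"] for r in res])

    def predict(self, X) -> np.ndarray:
        """Binary lesion masks [n, H, W]."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def predict_class(self, X) -> np.ndarray:
        """Predicted tumor class per image (0 benign, 1 malignant)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        res = _predict(self.model_, list(X), threshold=self.threshold,
                       input_size=self.image_size)
        return np.array([r["class_index"] for r in res])

    def score(self, X, y) -> float:
        """Mean Dice of predicted masks against reference masks."""
        preds = self.predict(X)
        y = np.asarray(y)
        report = evaluate({i: preds[i] for i in range(len(preds))},
                          {i: y[i] for i in range(len(preds))},
                          threshold=self.threshold)
        return report.mdice
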