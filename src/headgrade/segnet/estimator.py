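"""scikit-learn style estimator wrapping the segmentation network."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import ImprovedResNetModel, ModelConfig, predict_mask
from .train import TrainSchedule, train_arrays

__all__ = ["ImprovedResNetSegmenter"]


class ImprovedResNetSegmenter(BaseEstimator):
    """Per-pixel head segmentation as a fit/predict estimator.

    Parameters mirror :class:`ModelConfig` and :class:`TrainSchedule`.
    ``fit`` expects ``X`` as an (n, H, W, 3) uint8 array (or list of such
    images, H = W = ``input_size``) and ``y`` as matching {0, 1} masks.

    Attributes (after fit)
    ----------------------
    model_ : ImprovedResNetModel
        Trained weights.
    history_ : dict
        Per-epoch train/val dice loss and per-iteration learning rate.
    """

    def __init__(self, stage_widths=(8, 16, 32, 64), blocks_per_stage=1,
                 stage_strides=(1, 2, 2, 2), head_widths=(16, 8, 1),
                 fusion_channels=8, dropout_rate=0.1, input_size=96,
                 lrelu_a=0.01, base_lr=0.1, second_lr=0.05,
                 switch_iteration=3000, momentum=0.9, epochs=20,
                 batch_size=8, clip_norm=5.0, threshold=0.5, seed=0):
        self.stage_widths = stage_widths
        self.blocks_per_stage = blocks_per_stage
        self.stage_strides = stage_strides
        self.head_widths = head_widths
        self.fusion_channels = fusion_channels
        self.dropout_rate = dropout_rate
        self.input_size = input_size
        self.lrelu_a = lrelu_a
        self.base_lr = base_lr
        self.second_lr = second_lr
        self.switch_iteration = switch_iteration
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.clip_norm = clip_norm
        self.threshold = threshold
        self.seed = seed

    def _config(self) -> ModelConfig:
        return ModelConfig(
            stage_widths=tuple(self.stage_widths),
            blocks_per_stage=self.blocks_per_stage,
            stage_strides=tuple(self.stage_strides),
            head_widths=tuple(self.head_widths),
            fusion_channels=self.fusion_channels,
            dropout_rate=self.dropout_rate,
            input_size=self.input_size,
            lrelu_a=self.lrelu_a,
        )

    def _schedule(self) -> TrainSchedule:
        return TrainSchedule(
            base_lr=self.base_lr, second_lr=self.second_lr,
            switch_iteration=self.switch_iteration, momentum=self.momentum,
            epochs=self.epochs, batch_size=self.batch_size,
            clip_norm=self.clip_norm, seed=self.seed,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3 or X.shape[:3] != y.shape:
            raise ValueError("X must be (n, H, W, 3) with y of shape (n, H, W)")
        self.model_ = ImprovedResNetModel(self._config(), seed=self.seed)
        self.history_ = train_arrays(self.model_, X, y, X_val, y_val,
                                     self._schedule())
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return np.stack([predict_mask(self.model_, img, self.threshold)
                         for img in np.asarray(X)])

    def predict_proba_map(self, X) -> np.ndarray:
        """Per-pixel head probabilities for inputs at the model size."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return self.model_.forward(np.asarray(X), train=False)

    def score(self, X, y) -> float:
        """Mean per-image IoU against ground-truth masks."""
        from ..metrics import iou
        preds = self.predict(X)
        return float(np.mean([iou(p, t) for p, t in zip(preds, np.asarray(y))]))
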