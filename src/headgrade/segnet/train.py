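"""Dice-loss training with momentum SGD and a stepped learning rate.

The reference schedule: base learning rate 0.001 for the first 3000
iterations, then 0.0005 for the subsequent iterations; momentum 0.9;
batch size 64; 200 epochs.  The scaled test profile uses the same rule at
smaller sizes.  Everything (weight init, shuffling, dropout) is seeded, so
a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io import DatasetManifest, read_image, read_mask
from ..preprocess import resize
from .model import ImprovedResNetModel, dice_loss, dice_loss_grad

__all__ = ["TrainSchedule", "train", "train_arrays", "learning_rate_at"]


@dataclass
class TrainSchedule:
    base_lr: float = 0.001
    second_lr: float = 0.0005
    switch_iteration: int = 3000
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 64
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0 or self.second_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")


def learning_rate_at(schedule: TrainSchedule, iteration: int) -> float:
    """Stepped learning rate as a function of the 0-based iteration index."""
    return schedule.base_lr if iteration < schedule.switch_iteration \
        else schedule.second_lr


def _sgd_step(model: ImprovedResNetModel, lr: float, momentum: float,
              clip_norm: float = 0.0) -> None:
    params = model.params()
    if clip_norm > 0:
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
        if total > clip_norm:
            scale = clip_norm / total
            for p in params:
                p.grad *= scale
    for p in params:
        p.velocity = momentum * p.velocity - lr * p.grad
        p.value += p.velocity
        p.zero_grad()


def train_arrays(model: ImprovedResNetModel, X: np.ndarray, Y: np.ndarray,
                 X_val: np.ndarray | None = None,
                 Y_val: np.ndarray | None = None,
                 schedule: TrainSchedule | None = None) -> dict:
    """Train on in-memory arrays X (n, H, W, 3) and Y (n, H, W) in {0, 1}.

    Returns a history dict with per-epoch train/val dice loss and the
    learning rate used at every iteration.
    """
    if schedule is None:
        schedule = TrainSchedule()
    X = np.asarray(X)
    Y = np.asarray(Y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(schedule.seed)
    history: dict = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    iteration = 0
    n = len(X)
    for epoch in range(schedule.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            prob = model.forward(X[idx], train=True)
            losses.append(dice_loss(prob, Y[idx]))
            model.backward(dice_loss_grad(prob, Y[idx]))
            lr = learning_rate_at(schedule, iteration)
            history["lr"].append(lr)
            _sgd_step(model, lr, schedule.momentum, schedule.clip_norm)
            iteration += 1
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        if X_val is not None and len(X_val):
            vprob = model.forward(np.asarray(X_val), train=False)
            history["val_loss"].append(dice_loss(vprob, np.asarray(Y_val, dtype=float)))
        else:
            history["val_loss"].append(float("nan"))
    return history


def _load_pairs(manifest: DatasetManifest, size: int):
    xs, ys = [], []
    for rec in manifest.records:
        if not rec.mask_path:
            raise ValueError(f"record {rec.image_path} has no mask")
        img = read_image(manifest.resolve(rec.image_path))
        msk = read_mask(manifest.resolve(rec.mask_path))
        if img.shape[:2] != (size, size):
            img = resize(img, size, size, mode="bilinear")
            msk = resize(msk, size, size, mode="nearest")
        xs.append(img)
        ys.append(msk)
    return np.stack(xs), np.stack(ys)


def train(model: ImprovedResNetModel, train_manifest: DatasetManifest,
          val_manifest: DatasetManifest | None = None,
          schedule: TrainSchedule | None = None):
    """Train from dataset manifests; images are resized to the model input.

    Returns (model, history).
    """
    if len(train_manifest.records) == 0:
        raise ValueError("empty training manifest")
    size = model.config.input_size
    X, Y = _load_pairs(train_manifest, size)
    Xv = Yv = None
    if val_manifest is not None and len(val_manifest.records):
        Xv, Yv = _load_pairs(val_manifest, size)
    history = train_arrays(model, X, Y, Xv, Yv, schedule)
    return model, history
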