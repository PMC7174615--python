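"""The Improved-ResNet segmentation model.

Topology: a residual encoder of four stages (M1..M4).  Every stage output
is brought back to input resolution by its own transposed-convolution
branch; the four branch outputs are fused as a softmax-weighted sum with
learned scalar weights; the fused grid passes through a three-layer 1x1
convolution head (N1..N3) with LReLUSoftplus after N1 and N2, dropout
before N1, and a logistic output after N3, giving a per-pixel head
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import relu
from .layers import (ActLReLUSoftplus, BlockUpsample, Conv2d, Dropout, Param,
                     ResidualBlock)

__all__ = ["ModelConfig", "ImprovedResNetModel", "build_model", "dice_loss",
           "dice_loss_grad", "residual_block_forward", "predict_mask",
           "save_checkpoint", "load_checkpoint"]

DICE_EPS = 1.0


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults are the scaled profile used throughout the test suite; the
    ``full_profile`` uses the full-width encoder with its original
    hyper-parameters (dropout 0.8).
    """

    stage_widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    blocks_per_stage: int = 1
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    head_widths: tuple[int, int, int] = (16, 8, 1)
    fusion_channels: int = 8
    dropout_rate: float = 0.1
    input_size: int = 96
    lrelu_a: float = 0.01

    def __post_init__(self) -> None:
        if len(self.stage_widths) != 4 or len(self.stage_strides) != 4:
            raise ValueError("exactly four residual stages are required")
        if len(self.head_widths) != 3:
            raise ValueError("the adaptive head has exactly three layers")
        if self.head_widths[-1] != 1:
            raise ValueError("the last head layer must output one channel")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        total = int(np.prod(self.stage_strides))
        if self.input_size % total:
            raise ValueError(f"input_size must be divisible by {total}")

    @classmethod
    def full_profile(cls) -> "ModelConfig":
        return cls(stage_widths=(64, 128, 256, 512), blocks_per_stage=2,
                   stage_strides=(2, 2, 2, 2), head_widths=(64, 32, 1),
                   fusion_channels=32, dropout_rate=0.8, input_size=352)

    @classmethod
    def test_profile(cls) -> "ModelConfig":
        return cls()


class ImprovedResNetModel:
    """Weights plus forward/backward passes; built by :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = config
        self.stages: list[list[ResidualBlock]] = []
        in_ch = 3
        for width, stride in zip(cfg.stage_widths, cfg.stage_strides):
            blocks = [ResidualBlock(rng, in_ch, width, stride=stride)]
            for _ in range(cfg.blocks_per_stage - 1):
                blocks.append(ResidualBlock(rng, width, width, stride=1))
            self.stages.append(blocks)
            in_ch = width
        scales = np.cumprod(cfg.stage_strides)
        self.branches = [
            BlockUpsample(rng, w, cfg.fusion_channels, int(s))
            for w, s in zip(cfg.stage_widths, scales)
        ]
        self.fusion_w = Param(np.zeros(4))
        self.dropout = Dropout(cfg.dropout_rate, rng)
        widths = [cfg.fusion_channels, *cfg.head_widths]
        self.head = []
        for i in range(3):
            self.head.append(Conv2d(rng, widths[i], widths[i + 1], kernel=1))
            if i < 2:
                self.head.append(ActLReLUSoftplus(cfg.lrelu_a))
        self._cache = None

    # -- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for blocks in self.stages:
            for blk in blocks:
                ps.extend(blk.params())
        for br in self.branches:
            ps.extend(br.params())
        ps.append(self.fusion_w)
        for layer in self.head:
            ps.extend(getattr(layer, "params", list)())
        return ps

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _bn_layers(self):
        for blocks in self.stages:
            for blk in blocks:
                yield blk.bn1
                yield blk.bn2
                if blk.bn_proj is not None:
                    yield blk.bn_proj

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays: parameters plus batch-norm running stats."""
        arrays = [p.value for p in self.params()]
        for bn in self._bn_layers():
            arrays.extend([bn.run_mean, bn.run_var])
        return arrays

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, H, W, 3) uint8/float in [0, 255] -> (N, H, W) probabilities."""
        z = np.ascontiguousarray(
            np.asarray(x, dtype=float).transpose(0, 3, 1, 2)) / 255.0
        feats = []
        for blocks in self.stages:
            for blk in blocks:
                z = blk.forward(z, train)
            feats.append(z)
        branch_out = [br.forward(f, train) for br, f in zip(self.branches, feats)]
        ew = np.exp(self.fusion_w.value - self.fusion_w.value.max())
        s = ew / ew.sum()
        fused = sum(si * bi for si, bi in zip(s, branch_out))
        h = self.dropout.forward(fused, train)
        for layer in self.head:
            h = layer.forward(h, train)
        logits = h[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._cache = (branch_out, s, prob)
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dprob."""
        branch_out, s, prob = self._cache
        dlogits = dprob * prob * (1.0 - prob)
        dh = dlogits[:, None, :, :]
        for layer in reversed(self.head):
            dh = layer.backward(dh)
        dfused = self.dropout.backward(dh)
        ds = np.array([float((dfused * b).sum()) for b in branch_out])
        self.fusion_w.grad += s * (ds - float((s * ds).sum()))
        dfeats = [br.backward(s_i * dfused)
                  for br, s_i in zip(self.branches, s)]
        dz = dfeats[-1]
        for i in range(3, -1, -1):
            for blk in reversed(self.stages[i]):
                dz = blk.backward(dz)
            if i > 0:
                dz = dz + dfeats[i - 1]

    def fusion_softmax(self) -> np.ndarray:
        ew = np.exp(self.fusion_w.value - self.fusion_w.value.max())
        return ew / ew.sum()


def build_model(config: ModelConfig, seed: int = 0) -> ImprovedResNetModel:
    """Construct an untrained model; deterministic per (config, seed)."""
    return ImprovedResNetModel(config, seed=seed)


# -- dice loss -----------------------------------------------------------

def dice_loss(prob: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 - (2 sum(p t) + eps) / (sum p + sum t + eps), mean over samples."""
    prob = np.asarray(prob, dtype=float)
    target = np.asarray(target, dtype=float)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    if prob.ndim == 2:
        prob, target = prob[None], target[None]
    inter = (prob * target).sum(axis=(1, 2))
    sums = prob.sum(axis=(1, 2)) + target.sum(axis=(1, 2))
    return float(np.mean(1.0 - (2.0 * inter + eps) / (sums + eps)))


def dice_loss_grad(prob: np.ndarray, target: np.ndarray,
                   eps: float = DICE_EPS) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    target = np.asarray(target, dtype=float)
    squeeze = prob.ndim == 2
    if squeeze:
        prob, target = prob[None], target[None]
    n = prob.shape[0]
    inter = (prob * target).sum(axis=(1, 2))[:, None, None]
    sums = (prob.sum(axis=(1, 2)) + target.sum(axis=(1, 2)))[:, None, None]
    grad = -(2.0 * target * (sums + eps) - (2.0 * inter + eps)) / (sums + eps) ** 2
    grad = grad / n
    return grad[0] if squeeze else grad


# -- functional residual block: y = F(x, W1, W2) + Ws x ------------------

def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct stride-1 'same' convolution; x (C, H, W), w (O, C, k, k)."""
    o, c, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    return np.einsum("chwab,ocab->ohw", win, w, optimize=True)


def residual_block_forward(x: np.ndarray, W1: np.ndarray, W2: np.ndarray,
                           Ws: np.ndarray | None = None) -> np.ndarray:
    """One residual transform y = F(x, W1, W2) + Ws x.

    F is conv(W1) -> ReLU -> conv(W2); ``Ws`` is a channel-mixing matrix
    (out_ch, in_ch) applied per pixel, or None for the identity skip.
    """
    x = np.asarray(x, dtype=float)
    f = _conv_same(relu(_conv_same(x, W1)), W2)
    if Ws is None:
        if f.shape != x.shape:
            raise ValueError("identity skip requires matching channel counts")
        return f + x
    skip = np.einsum("oc,chw->ohw", np.asarray(Ws, dtype=float), x)
    return f + skip


# -- inference -----------------------------------------------------------

def predict_mask(model: ImprovedResNetModel, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Segment one (H, W, 3) image into a {0, 1} head mask.

    Images larger than the model input are processed as overlapping tiles
    whose probabilities are averaged; smaller images are reflection-padded
    and cropped back.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("predict_mask expects an (H, W, 3) image")
    size = model.config.input_size
    h, w = image.shape[:2]
    if (h, w) == (size, size):
        prob = model.forward(image[None], train=False)[0]
        return (prob > threshold).astype(np.uint8)
    ph, pw = max(size, h), max(size, w)
    padded = np.pad(image, ((0, ph - h), (0, pw - w), (0, 0)), mode="reflect")
    acc = np.zeros((ph, pw))
    cnt = np.zeros((ph, pw))
    step = max(1, size // 2)
    rows = sorted({min(r, ph - size) for r in range(0, ph, step)})
    cols = sorted({min(c, pw - size) for c in range(0, pw, step)})
    for r in rows:
        for c in cols:
            tile = padded[r:r + size, c:c + size]
            prob = model.forward(tile[None], train=False)[0]
            acc[r:r + size, c:c + size] += prob
            cnt[r:r + size, c:c + size] += 1.0
    prob = (acc / cnt)[:h, :w]
    return (prob > threshold).astype(np.uint8)


# -- checkpoints ---------------------------------------------------------

def save_checkpoint(model: ImprovedResNetModel, path, schedule=None) -> None:
    """Serialize weights + config (+ optional training schedule) to .npz."""
    meta = {"config": asdict(model.config), "seed": model.seed}
    if schedule is not None:
        meta["schedule"] = asdict(schedule)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ImprovedResNetModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = meta["config"]
        for key in ("stage_widths", "stage_strides", "head_widths"):
            cfg[key] = tuple(cfg[key])
        model = ImprovedResNetModel(ModelConfig(**cfg), seed=meta["seed"])
        for i, a in enumerate(model.state_arrays()):
            a[...] = data[f"p{i}"]
    return model
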