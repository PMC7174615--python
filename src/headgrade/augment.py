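"""Dataset expansion: random crops, right-angle rotations, fancy-PCA color
jitter, and a leakage-safe train/val/test split.

Each labeled original expands to exactly 12 outputs: 3 random crops, each
kept at 4 rotations (0, 90, 180, 270 degrees — the unrotated crop counts),
and every output receives an independent fancy-PCA color perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (DatasetManifest, SampleRecord, load_annotation, rasterize_polygons,
                 read_image, read_mask, save_manifest, write_image, write_mask)
from .preprocess import resize

__all__ = [
    "AugmentConfig",
    "random_crops",
    "rotations",
    "fpca_jitter",
    "augment_dataset",
    "split_dataset",
]

ROTATION_DEGREES = (0, 90, 180, 270)


@dataclass
class AugmentConfig:
    """Sizes are (width, height) pixel pairs."""

    resize_to: tuple[int, int] = (1440, 1080)
    crop_size: tuple[int, int] = (480, 360)
    crops_per_image: int = 3
    fpca_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size[0] > self.resize_to[0] or self.crop_size[1] > self.resize_to[1]:
            raise ValueError("crop_size must fit inside resize_to")
        if self.crops_per_image < 1:
            raise ValueError("crops_per_image must be >= 1")
        if self.fpca_sigma < 0:
            raise ValueError("fpca_sigma must be >= 0")


def random_crops(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator | None = None):
    """Crop ``crops_per_image`` aligned (image, mask) pairs.

    Crop origins are uniform over all valid top-left positions; the same
    box is applied to image and mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes differ")
    cw, ch = config.crop_size
    h, w = image.shape[:2]
    if ch > h or cw > w:
        raise ValueError(f"crop {cw}x{ch} larger than image {w}x{h}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.crops_per_image):
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        out.append((image[r0:r0 + ch, c0:c0 + cw].copy(),
                    mask[r0:r0 + ch, c0:c0 + cw].copy()))
    return out


def rotations(image: np.ndarray, mask: np.ndarray):
    """Original plus 90/180/270-degree rotations, masks rotated identically."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes differ")
    return [(np.rot90(image, k).copy(), np.rot90(mask, k).copy()) for k in range(4)]


def fpca_jitter(image: np.ndarray, sigma: float = 0.1, seed: int = 0) -> np.ndarray:
    """Fancy-PCA color perturbation.

    The 3x3 covariance of mean-centered RGB values (on the [0, 1] scale) is
    eigen-decomposed into (p_i, lambda_i); one draw alpha_i ~ N(0, sigma)
    per image adds sum_i p_i * alpha_i * lambda_i to every pixel, shifting
    global illumination/color without moving object boundaries.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("fpca_jitter expects an (H, W, 3) image")
    if sigma == 0:
        return image.copy()
    flat = image.reshape(-1, 3).astype(float) / 255.0
    cov = np.cov(flat - flat.mean(axis=0), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, sigma, size=3)
    delta = eigvecs @ (alpha * eigvals)  # same shift at every pixel
    out = image.astype(float) + delta * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _record_mask(manifest: DatasetManifest, rec: SampleRecord, shape) -> np.ndarray:
    if rec.mask_path:
        return read_mask(manifest.resolve(rec.mask_path))
    if rec.annotation_path:
        ann = load_annotation(manifest.resolve(rec.annotation_path))
        return rasterize_polygons(ann, shape[0], shape[1])
    raise ValueError(f"record {rec.image_path} has neither mask nor annotation")


def augment_dataset(manifest: DatasetManifest, config: AugmentConfig,
                    out_dir: str | Path) -> DatasetManifest:
    """Expand every labeled record 12x and write the result to ``out_dir``.

    Output records carry provenance columns ``source_id``, ``crop_idx`` and
    ``rotation_deg`` so splits can be made leakage-safe.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tw, th = config.resize_to
    records: list[SampleRecord] = []
    for src_idx, rec in enumerate(manifest.records):
        image = read_image(manifest.resolve(rec.image_path))
        mask = _record_mask(manifest, rec, image.shape)
        image = resize(image, tw, th, mode="bilinear")
        mask = resize(mask, tw, th, mode="nearest")
        rng = np.random.default_rng(config.seed + src_idx)
        stem = Path(rec.image_path).stem
        for crop_idx, (ci, cm) in enumerate(random_crops(image, mask, config, rng)):
            for rot_idx, (ri, rm) in enumerate(rotations(ci, cm)):
                deg = ROTATION_DEGREES[rot_idx]
                jit_seed = int(rng.integers(0, 2**31 - 1))
                ri = fpca_jitter(ri, config.fpca_sigma, seed=jit_seed)
                img_rel = f"{stem}_c{crop_idx}_r{deg}.png"
                mask_rel = f"{stem}_c{crop_idx}_r{deg}_mask.png"
                write_image(ri, out_dir / img_rel)
                write_mask(rm, out_dir / mask_rel)
                records.append(SampleRecord(
                    image_path=img_rel,
                    mask_path=mask_rel,
                    weight_g=rec.weight_g,
                    variety=rec.variety,
                    acquisition=rec.acquisition,
                    extra={
                        "source_id": str(src_idx),
                        "crop_idx": str(crop_idx),
                        "rotation_deg": str(deg),
                    },
                ))
    out = DatasetManifest(records=records, root=out_dir)
    save_manifest(out, out_dir / "manifest.csv")
    return out


def _parse_ratio(ratio) -> tuple[float, ...]:
    if isinstance(ratio, str):
        parts = tuple(float(p) for p in ratio.split(":"))
    else:
        parts = tuple(float(p) for p in ratio)
    if len(parts) != 3 or any(p <= 0 for p in parts):
        raise ValueError(f"ratio must be three positive parts, got {ratio!r}")
    return parts


def split_dataset(manifest: DatasetManifest, ratio="6:1:1", seed: int = 0):
    """Partition into (train, val, test) by source image.

    Records sharing a ``source_id`` (i.e. crops/rotations of one original)
    always land in the same split.  Groups are shuffled by ``seed`` and
    assigned greedily to the split with the largest remaining deficit, so
    counts are as close to the requested ratio as group atomicity allows.
    """
    parts = _parse_ratio(ratio)
    groups: dict[str, list[SampleRecord]] = {}
    for rec in manifest.records:
        key = rec.extra.get("source_id", rec.image_path)
        groups.setdefault(key, []).append(rec)
    keys = sorted(groups)
    if len(keys) < len(parts):
        raise ValueError(f"only {len(keys)} source groups for a {len(parts)}-way split")
    rng = np.random.default_rng(seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    total = len(manifest.records)
    targets = [total * p / sum(parts) for p in parts]
    counts = [0, 0, 0]
    buckets: list[list[SampleRecord]] = [[], [], []]
    for key in order:
        deficits = [t - c for t, c in zip(targets, counts)]
        j = int(np.argmax(deficits))
        buckets[j].extend(groups[key])
        counts[j] += len(groups[key])
    return tuple(manifest.with_records(b) for b in buckets)
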