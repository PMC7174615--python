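"""Synthetic broccoli-field scenes with exact ground truth.

Real acquisitions of this kind are nadir RGB photographs of broccoli beds:
a soil background, one or a few dense green heads per frame, occasional
occluding leaves, and — on ageing heads — patches of yellowing flower buds.
This module renders simplified scenes with the same structure and returns
pixel-exact ground truth (head mask, yellow-bud mask, fresh weight), which
makes every downstream stage testable without field data.

The fresh-weight ground truth follows the linear pixel-area model used for
yield estimation: ``weight = k * head_area_px + noise``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .io import DatasetManifest, SampleRecord, save_manifest, write_image, write_mask

__all__ = [
    "SceneParams",
    "SyntheticSample",
    "GenerationError",
    "generate_scene",
    "generate_dataset",
    "add_noise",
    "adjust_illumination",
]

# Base colors (R, G, B); the granular texture modulates luminance only, so
# chromatic contrasts between classes are stable.
SOIL_RGB = (124.0, 92.0, 62.0)
HEAD_RGB = (58.0, 128.0, 52.0)
YELLOW_RGB = (205.0, 200.0, 70.0)
LEAF_RGB = (38.0, 88.0, 44.0)

NOISE_KINDS = ("gaussian", "salt_pepper", "rayleigh")


class GenerationError(RuntimeError):
    """Scene geometry could not be realized (e.g. heads cannot be placed)."""


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    Defaults emulate a 480x360 crop around a single plant, the working
    resolution of the augmented training data.  ``weight_coeff_k`` is in
    grams per head pixel, ``weight_noise_sd`` in grams.
    """

    height: int = 360
    width: int = 480
    n_heads: int = 1
    head_radius_range: tuple[float, float] = (50.0, 95.0)
    bud_granule_size: int = 4
    yellow_fraction: float = 0.0
    leaf_occlusion_fraction: float = 0.10
    weight_coeff_k: float = 0.002
    weight_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.head_radius_range
        if not (0 < lo <= hi):
            raise ValueError("head_radius_range must satisfy 0 < lo <= hi")
        if 2 * hi > min(self.height, self.width):
            raise ValueError("head radii do not fit in the canvas")
        if not 0.0 <= self.yellow_fraction <= 1.0:
            raise ValueError("yellow_fraction must be in [0, 1]")
        if not 0.0 <= self.leaf_occlusion_fraction < 1.0:
            raise ValueError("leaf_occlusion_fraction must be in [0, 1)")
        if self.weight_coeff_k <= 0:
            raise ValueError("weight_coeff_k must be > 0")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be >= 0")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.bud_granule_size < 1:
            raise ValueError("bud_granule_size must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["head_radius_range"] = list(d["head_radius_range"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneParams":
        d = yaml.safe_load(Path(path).read_text())
        if "head_radius_range" in d:
            d["head_radius_range"] = tuple(d["head_radius_range"])
        return cls(**d)


@dataclass
class SyntheticSample:
    image: np.ndarray        # (H, W, 3) uint8
    head_mask: np.ndarray    # (H, W) {0, 1}
    yellow_mask: np.ndarray  # (H, W) {0, 1}, subset of head_mask
    true_weight_g: float
    true_yellow_fraction: float


def _luminance_texture(rng: np.random.Generator, h: int, w: int,
                       scale: int, amplitude: float) -> np.ndarray:
    """Blocky brightness modulation with feature size ~``scale`` pixels."""
    gh, gw = max(1, math.ceil(h / scale)), max(1, math.ceil(w / scale))
    coarse = rng.standard_normal((gh, gw))
    fine = np.kron(coarse, np.ones((scale, scale)))[:h, :w]
    fine = ndimage.gaussian_filter(fine, sigma=scale / 3.0)
    sd = fine.std()
    if sd > 0:
        fine = fine / sd
    return fine * amplitude


def _ellipse_mask(h: int, w: int, cr: float, cc: float,
                  a: float, b: float, theta: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:h, 0:w]
    dy, dx = rr - cr, cc_ - cc
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_heads(params: SceneParams, rng: np.random.Generator) -> list[np.ndarray]:
    h, w = params.height, params.width
    lo, hi = params.head_radius_range
    heads: list[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_heads):
        for _attempt in range(60):
            a = rng.uniform(lo, hi)
            b = a * rng.uniform(0.75, 1.0)
            theta = rng.uniform(0, math.pi)
            r_ext = max(a, b)
            if h - 2 * r_ext <= 1 or w - 2 * r_ext <= 1:
                continue
            cr = rng.uniform(r_ext, h - r_ext)
            cc = rng.uniform(r_ext, w - r_ext)
            m = _ellipse_mask(h, w, cr, cc, a, b, theta)
            if not (m & occupied).any():
                heads.append(m)
                occupied |= ndimage.binary_dilation(m, iterations=3)
                break
        else:
            raise GenerationError(
                f"could not place {params.n_heads} non-overlapping heads "
                f"in a {h}x{w} canvas"
            )
    return heads


def _grow_yellow(head: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing inside ``head`` until exactly ``target`` pixels."""
    h, w = head.shape
    patch = np.zeros_like(head, dtype=bool)
    if target <= 0:
        return patch
    in_rows, in_cols = np.nonzero(head)
    n_seeds = max(1, target // 400)
    order = rng.permutation(in_rows.size)[:n_seeds]
    frontier: list[tuple[int, int]] = []
    count = 0

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and head[rr, cc] and not patch[rr, cc]:
                frontier.append((rr, cc))

    for idx in order:
        r, c = int(in_rows[idx]), int(in_cols[idx])
        if not patch[r, c]:
            patch[r, c] = True
            count += 1
            push_neighbors(r, c)
            if count >= target:
                return patch
    while frontier and count < target:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        r, c = frontier.pop()
        if patch[r, c]:
            continue
        patch[r, c] = True
        count += 1
        push_neighbors(r, c)
    return patch


def _occlude_with_leaves(head: np.ndarray, params: SceneParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Leaf lobes overdrawing up to ``leaf_occlusion_fraction`` of the head."""
    budget = int(params.leaf_occlusion_fraction * int(head.sum()))
    leaves = np.zeros_like(head, dtype=bool)
    if budget <= 0:
        return leaves
    h, w = head.shape
    rows, cols = np.nonzero(head)
    removed = 0
    for _ in range(30):
        if removed >= 0.8 * budget:
            break
        i = int(rng.integers(rows.size))
        cr, cc = float(rows[i]), float(cols[i])
        a = rng.uniform(8, 25)
        b = a * rng.uniform(0.4, 0.8)
        lobe = _ellipse_mask(h, w, cr, cc, a, b, rng.uniform(0, math.pi))
        new = lobe & head & ~leaves
        if removed + int(new.sum()) > budget:
            continue
        leaves |= lobe
        removed += int(new.sum())
    return leaves


def generate_scene(params: SceneParams) -> SyntheticSample:
    """Render one scene; bit-deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    img = np.empty((h, w, 3), dtype=float)
    img[:] = SOIL_RGB
    img += _luminance_texture(rng, h, w, scale=10, amplitude=14.0)[:, :, None]

    heads = _place_heads(params, rng)
    head_mask = np.zeros((h, w), dtype=bool)
    for m in heads:
        head_mask |= m

    granule = _luminance_texture(rng, h, w, scale=params.bud_granule_size,
                                 amplitude=16.0)
    img[head_mask] = np.asarray(HEAD_RGB) + granule[head_mask, None]

    # Occluding leaves first, then bud yellowing on what remains visible, so
    # the recorded yellow fraction refers to the visible head.
    leaves = np.zeros((h, w), dtype=bool)
    for m in heads:
        leaves |= _occlude_with_leaves(m, params, rng)
    leaf_all = leaves
    if leaf_all.any():
        img[leaf_all] = np.asarray(LEAF_RGB) + granule[leaf_all, None] * 0.3
    head_mask &= ~leaf_all

    n_head = int(head_mask.sum())
    yellow_mask = np.zeros((h, w), dtype=bool)
    if params.yellow_fraction > 0 and n_head > 0:
        target = int(round(params.yellow_fraction * n_head))
        yellow_mask = _grow_yellow(head_mask, target, rng)
        img[yellow_mask] = np.asarray(YELLOW_RGB) + granule[yellow_mask, None]

    # Small per-channel jitter; kept tiny so class chromaticity dominates.
    img += rng.normal(0.0, 1.0, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    true_fraction = float(yellow_mask.sum()) / n_head if n_head else 0.0
    weight = params.weight_coeff_k * n_head
    if params.weight_noise_sd > 0:
        weight += float(rng.normal(0.0, params.weight_noise_sd))
    weight = max(weight, 0.0)

    return SyntheticSample(
        image=image,
        head_mask=head_mask.astype(np.uint8),
        yellow_mask=yellow_mask.astype(np.uint8),
        true_weight_g=weight,
        true_yellow_fraction=true_fraction,
    )


def generate_dataset(params: SceneParams, n: int, out_dir: str | Path) -> DatasetManifest:
    """Write ``n`` scenes (image + masks) plus a CSV manifest to ``out_dir``.

    Per-scene seeds are derived as ``params.seed + index`` so any scene can
    be regenerated in isolation.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n):
        p = SceneParams(**{**asdict(params), "seed": params.seed + i,
                           "head_radius_range": params.head_radius_range})
        sample = generate_scene(p)
        img_rel = f"scene_{i:04d}.png"
        mask_rel = f"scene_{i:04d}_mask.png"
        ymask_rel = f"scene_{i:04d}_yellow.png"
        write_image(sample.image, out_dir / img_rel)
        write_mask(sample.head_mask, out_dir / mask_rel)
        write_mask(sample.yellow_mask, out_dir / ymask_rel)
        records.append(SampleRecord(
            image_path=img_rel,
            mask_path=mask_rel,
            weight_g=sample.true_weight_g if sample.true_weight_g > 0 else None,
            variety="synthetic",
            acquisition="S1",
            extra={
                "yellow_mask_path": ymask_rel,
                "true_yellow_fraction": f"{sample.true_yellow_fraction:.6f}",
            },
        ))
    manifest = DatasetManifest(records=records, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def add_noise(image: np.ndarray, kind: str, level: float, seed: int = 0) -> np.ndarray:
    """Corrupt an image with one of the benchmark noise models.

    ``gaussian`` adds N(0, level*255) per channel; ``salt_pepper`` sets each
    pixel (all channels) to 0 or 255 with probability level/2 each;
    ``rayleigh`` adds mean-centered Rayleigh(scale=level*255) noise so that
    level -> 0 limits to the identity.  Output is clipped to [0, 255].
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    if level < 0:
        raise ValueError("level must be >= 0")
    image = np.asarray(image)
    if level == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    x = image.astype(float)
    if kind == "gaussian":
        x = x + rng.normal(0.0, level * 255.0, size=x.shape)
    elif kind == "rayleigh":
        scale = level * 255.0
        noise = rng.rayleigh(scale, size=x.shape)
        x = x + noise - scale * math.sqrt(math.pi / 2.0)
    else:  # salt_pepper
        u = rng.random(x.shape[:2])
        x = x.copy()
        x[u < level / 2.0] = 0.0
        x[(u >= level / 2.0) & (u < level)] = 255.0
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def adjust_illumination(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale all channels by ``factor`` (a brightness multiplier) and clip.

    Emulates acquisition under brighter or dimmer illumination; the mapping
    from physical illuminance to pixel values is camera-specific, so the
    harness exposes the multiplicative factor directly.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    x = np.asarray(image).astype(float) * factor
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)
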