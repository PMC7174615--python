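"""Background denoising and resizing.

The denoising stage follows the classical recipe for near-ground field
imagery: a Roberts cross operator exposes high-frequency edges (useful as a
quality-control layer for head/bud scale), and a 3x3 median filter removes
impulse noise.  The two are kept separate — the filtered image is what flows
downstream, the edge map is diagnostic output only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["to_gray", "robert_edges", "median_filter3", "resize", "denoise"]

LUMA = (0.299, 0.587, 0.114)


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB -> luminance (float); single-channel input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ np.asarray(LUMA)
    raise ValueError(f"expected (H, W) or (H, W, 3), got {image.shape}")


def robert_edges(gray_image: np.ndarray) -> np.ndarray:
    """Roberts-cross gradient magnitude, edge-replicated to input shape.

    d1 = I[r, c] - I[r+1, c+1] and d2 = I[r, c+1] - I[r+1, c]; the output is
    sqrt(d1^2 + d2^2) per pixel, with the last row/column padded by edge
    replication so the result is H x W.
    """
    g = np.asarray(to_gray(gray_image), dtype=float)
    if g.size == 0 or g.ndim != 2:
        raise ValueError("robert_edges requires a nonempty 2-D image")
    p = np.pad(g, ((0, 1), (0, 1)), mode="edge")
    d1 = p[:-1, :-1] - p[1:, 1:]
    d2 = p[:-1, 1:] - p[1:, :-1]
    return np.sqrt(d1 * d1 + d2 * d2)


def median_filter3(image: np.ndarray) -> np.ndarray:
    """3x3 median filter per channel with reflection at the borders."""
    image = np.asarray(image)
    if image.ndim not in (2, 3) or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("median_filter3 requires an image of at least 3x3 pixels")
    # scipy's "mirror" is edge reflection without repeating the border pixel
    if image.ndim == 2:
        return ndimage.median_filter(image, size=3, mode="mirror")
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[:, :, ch] = ndimage.median_filter(image[:, :, ch], size=3, mode="mirror")
    return out


def resize(image: np.ndarray, width: int, height: int, mode: str = "bilinear") -> np.ndarray:
    """Resize to (height, width); ``bilinear`` for images, ``nearest`` for masks."""
    if width < 1 or height < 1:
        raise ValueError("target dimensions must be >= 1")
    if mode not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resize mode {mode!r}")
    image = np.asarray(image)
    if image.shape[0] == height and image.shape[1] == width:
        return image.copy()
    shape = (height, width) + image.shape[2:]
    order = 1 if mode == "bilinear" else 0
    out = _sk_resize(image.astype(float), shape, order=order,
                     mode="edge", anti_aliasing=(mode == "bilinear"),
                     preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def denoise(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-filter the image; return it with the Roberts edge map of the
    original as a diagnostic layer."""
    edges = robert_edges(image)
    return median_filter3(image), edges
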