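"""Image, mask, annotation and manifest I/O.

Conventions used throughout the package: coordinates are 0-based with the
origin at the top-left, arrays are row-major (``array[row, col]``), and
boxes are half-open ``[r0, r1) x [c0, c1)``.  Labelme-style polygon points
are ``(x, y)`` pairs with x = column and y = row.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "SampleRecord",
    "DatasetManifest",
    "FormatError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "rasterize_polygons",
    "load_annotation",
    "load_manifest",
    "save_manifest",
]

MANIFEST_COLUMNS = [
    "image_path",
    "mask_path",
    "annotation_path",
    "weight_g",
    "variety",
    "acquisition",
]


class FormatError(ValueError):
    """Raised when a file exists but cannot be decoded as expected."""


@dataclass
class SampleRecord:
    """One dataset row: an image plus its labels and metadata.

    For supervised use at least one of ``mask_path`` / ``annotation_path``
    must be present; ``weight_g`` must be positive when given.
    """

    image_path: str
    mask_path: str | None = None
    annotation_path: str | None = None
    weight_g: float | None = None
    variety: str = ""
    acquisition: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight_g is not None and not self.weight_g > 0:
            raise ValueError(f"weight_g must be > 0, got {self.weight_g}")


@dataclass
class DatasetManifest:
    """Ordered collection of sample records rooted at a directory."""

    records: list[SampleRecord]
    root: Path = Path(".")

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image paths in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def resolve(self, rel: str) -> Path:
        return self.root / rel

    def with_records(self, records: list[SampleRecord]) -> "DatasetManifest":
        return DatasetManifest(records=records, root=self.root)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image as an (H, W, 3) uint8 array.

    Grayscale inputs are promoted by channel replication; an alpha channel
    is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # undecodable / truncated
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise FormatError(f"{path}: expected 8-bit image, got {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported image shape {arr.shape}")
    return np.ascontiguousarray(arr)


def write_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    iio.imwrite(Path(path), image.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from a single-channel {0, 255} PNG as {0, 1} uint8."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot decode mask {path}: {exc}") from exc
    if arr.ndim == 3:
        if not (arr == arr[:, :, :1]).all():
            raise ValueError(f"{path}: multi-channel mask with unequal channels")
        arr = arr[:, :, 0]
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"{path}: mask contains values other than 0/255: {bad[:5]}")
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.isin(mask, [0, 1]).all():
        raise ValueError("mask must be 2-D with values in {0, 1}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def rasterize_polygons(annotation: dict | Sequence, height: int, width: int) -> np.ndarray:
    """Rasterize Labelme-style polygons to a {0, 1} mask.

    A pixel (r, c) is set when its center (x = c, y = r) lies inside any
    polygon by the even-odd crossing rule (a rightward ray from the center
    crosses the boundary an odd number of times); the result is the union
    over shapes.  The rule makes boundary behavior deterministic: pixels on
    a left/top edge are inside, right/bottom edges outside.  Vertices
    outside the canvas are clipped to its bounds.

    Parameters
    ----------
    annotation : dict or sequence
        Either the full Labelme dict ``{"shapes": [{"points": [[x, y], ...]},
        ...]}`` or directly the list of shapes / point lists.
    """
    if isinstance(annotation, dict):
        shapes = annotation.get("shapes", [])
    else:
        shapes = list(annotation)
    mask = np.zeros((height, width), dtype=np.uint8)
    if not shapes:
        return mask
    xs = np.arange(width, dtype=float)[None, :, None]    # pixel-center x
    ys = np.arange(height, dtype=float)[:, None, None]   # pixel-center y
    for shape in shapes:
        pts = shape["points"] if isinstance(shape, dict) else shape
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError(f"polygon needs >= 3 (x, y) vertices, got {pts.shape}")
        px = np.clip(pts[:, 0], 0, width - 1)
        py = np.clip(pts[:, 1], 0, height - 1)
        x1, y1 = px[None, None, :], py[None, None, :]
        x2, y2 = np.roll(px, -1)[None, None, :], np.roll(py, -1)[None, None, :]
        straddles = (y1 > ys) != (y2 > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        crossings = (straddles & (xs < xin)).sum(axis=2)
        mask |= (crossings % 2 == 1).astype(np.uint8)
    return mask


def load_annotation(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation not found: {path}")
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"cannot parse annotation {path}: {exc}") from exc
    if "shapes" not in data:
        raise FormatError(f"{path}: not a Labelme-style annotation (no 'shapes')")
    return data


def load_manifest(path: str | Path, *, check_paths: bool = True) -> DatasetManifest:
    """Load a CSV manifest; paths are resolved relative to the CSV's directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    root = path.parent
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "image_path" not in reader.fieldnames:
            raise FormatError(f"{path}: manifest missing required column image_path")
        known = set(MANIFEST_COLUMNS)
        records = []
        for i, row in enumerate(reader):
            rec = SampleRecord(
                image_path=row["image_path"],
                mask_path=row.get("mask_path") or None,
                annotation_path=row.get("annotation_path") or None,
                weight_g=float(row["weight_g"]) if row.get("weight_g") else None,
                variety=row.get("variety", "") or "",
                acquisition=row.get("acquisition", "") or "",
                extra={k: v for k, v in row.items() if k not in known and v},
            )
            if check_paths and not (root / rec.image_path).exists():
                raise ValueError(f"{path} row {i}: unresolvable image_path {rec.image_path}")
            records.append(rec)
    return DatasetManifest(records=records, root=root)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extra_cols = sorted({k for r in manifest.records for k in r.extra})
    cols = MANIFEST_COLUMNS + extra_cols
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for r in manifest.records:
            row = {
                "image_path": r.image_path,
                "mask_path": r.mask_path or "",
                "annotation_path": r.annotation_path or "",
                "weight_g": "" if r.weight_g is None else repr(float(r.weight_g)),
                "variety": r.variety,
                "acquisition": r.acquisition,
            }
            row.update(r.extra)
            writer.writerow(row)
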