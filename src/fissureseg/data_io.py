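"""Reading and writing images, polygon annotations, and label masks.

Conventions used throughout the package:

* Images are ``(H, W, 3)`` uint8 arrays; masks are ``(H, W)`` uint8 arrays
  of class labels (0 = background, 1 = fissure).
* Polygon annotations follow the labelme JSON dialect: a top-level
  ``"shapes"`` list whose entries carry ``"label"`` and ``"points"``, plus
  ``"imageHeight"`` / ``"imageWidth"``.
* Polygon coordinates are 0-based ``(x, y)`` with the origin at the
  top-left corner, x rightward and y downward. A pixel ``(row r, col c)``
  belongs to a polygon iff its center ``(c + 0.5, r + 0.5)`` lies inside
  under the even-odd rule; overlapping polygons union.
* Mask PNG files store 0/255 for visibility; in memory labels are 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "AnnotationFormatError",
    "Sample",
    "PolygonAnnotation",
    "DatasetSplit",
    "read_annotation",
    "rasterize",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "split_dataset",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation or mask file violates the expected format."""


@dataclass
class Sample:
    """One image with an optional pixel-exact label mask."""

    image: np.ndarray
    mask: Optional[np.ndarray] = None
    identifier: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != image spatial shape {self.image.shape[:2]}"
                )


@dataclass
class PolygonAnnotation:
    """Named polygons in image coordinates, rasterizable to a mask."""

    shapes: list  # list of (label, points) with points an (n, 2) float array
    image_height: int
    image_width: int

    def __post_init__(self):
        cleaned = []
        for label, points in self.shapes:
            pts = np.asarray(points, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise AnnotationFormatError(
                    f"polygon '{label}' needs >= 3 (x, y) points, got shape {pts.shape}"
                )
            if not np.isfinite(pts).all():
                raise AnnotationFormatError(f"polygon '{label}' has non-finite coordinates")
            cleaned.append((label, pts))
        self.shapes = cleaned


@dataclass
class DatasetSplit:
    train_ids: list
    held_out_ids: list
    train_fraction: float
    seed: int


def read_annotation(path, fissure_label: Optional[str] = None) -> PolygonAnnotation:
    """Parse a labelme-dialect JSON annotation file.

    Parameters
    ----------
    path : str or Path
        JSON file with top-level ``shapes``, ``imageHeight``, ``imageWidth``.
    fissure_label : str, optional
        If given, keep only shapes whose ``label`` equals it; by default
        every shape is treated as a fissure polygon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in doc:
            raise AnnotationFormatError(f"{path}: missing required key '{key}'")
    shapes = []
    for i, shape in enumerate(doc["shapes"]):
        for key in ("label", "points"):
            if key not in shape:
                raise AnnotationFormatError(f"{path}: shape {i} missing required key '{key}'")
        if fissure_label is not None and shape["label"] != fissure_label:
            continue
        shapes.append((shape["label"], shape["points"]))
    return PolygonAnnotation(
        shapes=shapes,
        image_height=int(doc["imageHeight"]),
        image_width=int(doc["imageWidth"]),
    )


def _evenodd_inside(points: np.ndarray, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    Uses the standard half-open edge rule: an edge from (x1,y1) to (x2,y2)
    crosses the horizontal ray from (cx, cy) iff (y1 > cy) != (y2 > cy) and
    the x-intersection is strictly right of cx.
    """
    inside = np.zeros(cx.shape, dtype=bool)
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        cond = (y1 > cy) != (y2 > cy)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (cy - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (cx < xint)
    return inside


def rasterize(ann: PolygonAnnotation) -> np.ndarray:
    """Rasterize an annotation to an (H, W) uint8 mask of 0/1 labels.

    A pixel is labeled 1 iff its center lies inside any polygon under the
    even-odd rule (union over polygons).
    """
    h, w = ann.image_height, ann.image_width
    mask = np.zeros((h, w), dtype=np.uint8)
    if not ann.shapes:
        return mask
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    cx = cols + 0.5
    cy = rows + 0.5
    for _, pts in ann.shapes:
        mask |= _evenodd_inside(pts, cx, cy).astype(np.uint8)
    return mask


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG image as an (H, W, 3) uint8 array; grayscale is promoted."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Read a single-channel PNG mask; any nonzero pixel maps to label 1."""
    path = Path(path)
    with Image.open(path) as im:
        if im.format != "PNG":
            raise AnnotationFormatError(f"{path}: mask must be PNG, got {im.format}")
        if im.mode not in ("L", "1", "I", "I;16", "P"):
            raise AnnotationFormatError(
                f"{path}: mask must be single-channel, got mode '{im.mode}'"
            )
        arr = np.asarray(im.convert("I"))
    return (arr != 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a single-channel PNG storing 0/255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise AnnotationFormatError(f"mask must be 2-D, got shape {mask.shape}")
    Image.fromarray(((mask != 0) * np.uint8(255)), mode="L").save(path, format="PNG")


def split_dataset(ids: Sequence, train_fraction: float, seed: int) -> DatasetSplit:
    """Randomly partition identifiers into train / held-out sets.

    Train size is ``round(n * train_fraction)`` (banker's rounding as in
    python's round). Deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = round(len(ids) * train_fraction)
    train_ids = [ids[i] for i in order[:n_train]]
    held_out = [ids[i] for i in order[n_train:]]
    return DatasetSplit(train_ids, held_out, train_fraction, seed)
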