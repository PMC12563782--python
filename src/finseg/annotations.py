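"""Annotation I/O, polygon rasterization, and specimen-level dataset splitting.

Conventions used across the package:

* images are ``H x W x 3`` uint8 RGB numpy arrays, masks are ``H x W``
  integer rasters;
* all pixel coordinates are 0-based and half-open, so a box
  ``(x_min, y_min, x_max, y_max)`` covers pixel columns
  ``x_min .. x_max-1``;
* part masks use 0 = background, 1 = belly, 2 = loin, 3 = back;
  defect masks use 0 = none, 1 = fat, 2 = bruise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

logger = logging.getLogger(__name__)

#: closed label vocabulary: anatomical parts, defect classes, and the
#: whole-body "fish" label used by the background-removal task.
CLASS_VOCAB = ("belly", "loin", "back", "fat", "bruise", "fish")

#: raster index assigned to each polygon label.  Parts feed the 4-class
#: segmenter; "fish" feeds the 2-class background-removal model; the
#: defect labels feed the 3-class crop segmenter.
RASTER_INDEX = {"belly": 1, "loin": 2, "back": 3, "fish": 1, "fat": 1, "bruise": 2}

#: detector class ids (YOLO text files)
DEFECT_CLASS_NAMES = ("fat", "bruise")

#: palette for indexed-PNG masks: background, belly/fat, loin/bruise, back
MASK_PALETTE = [
    (0, 0, 0),
    (255, 0, 0),
    (0, 255, 0),
    (255, 255, 0),
]


class AnnotationError(ValueError):
    """Malformed annotation file."""


class VocabularyError(AnnotationError):
    """Label outside the closed class vocabulary."""


@dataclass
class PolygonLabel:
    class_name: str
    vertices: np.ndarray  # (n, 2) float (x, y)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.class_name not in CLASS_VOCAB:
            raise VocabularyError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_VOCAB}"
            )
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise AnnotationError("polygon needs >= 3 (x, y) vertices")


@dataclass
class BoundingBox:
    """Axis-aligned box in half-open pixel coordinates with a confidence."""

    class_id: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise AnnotationError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise AnnotationError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


@dataclass
class Split:
    train_ids: list[int]
    val_ids: list[int]
    test_ids: list[int]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise AnnotationError("split partitions overlap")

    @property
    def all_ids(self) -> set[int]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


# ---------------------------------------------------------------------------
# LabelMe-dialect polygon JSON
# ---------------------------------------------------------------------------

def read_polygon_annotations(path: str | Path) -> list[PolygonLabel]:
    """Read a LabelMe-style JSON file (``shapes`` with ``label``/``points``)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"{path}: invalid JSON ({e})") from e
    if not isinstance(doc, dict) or "shapes" not in doc:
        raise AnnotationError(f"{path}: missing 'shapes' array")
    labels = []
    for i, shape in enumerate(doc["shapes"]):
        if "label" not in shape or "points" not in shape:
            raise AnnotationError(f"{path}: shape {i} missing 'label' or 'points'")
        labels.append(PolygonLabel(shape["label"], np.asarray(shape["points"], float)))
    return labels


def write_polygon_annotations(labels: list[PolygonLabel], path: str | Path,
                              image_size: tuple[int, int] | None = None) -> None:
    doc: dict = {
        "version": "5.4.1",
        "shapes": [
            {
                "label": lb.class_name,
                "points": [[float(x), float(y)] for x, y in lb.vertices],
                "shape_type": "polygon",
            }
            for lb in labels
        ],
    }
    if image_size is not None:
        doc["imageHeight"], doc["imageWidth"] = int(image_size[0]), int(image_size[1])
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd crossing test, vectorized over query points."""
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cond = (y1 > ys) != (y2 > ys)
        if not cond.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (xs < xint)
    return inside


def rasterize_polygons(labels: list[PolygonLabel], size: tuple[int, int]) -> np.ndarray:
    """Rasterize polygons into a label mask at pixel centers (even-odd rule).

    Later polygons overwrite earlier ones where they overlap.  A
    zero-area polygon is skipped with a warning.
    """
    h, w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    for lb in labels:
        v = lb.vertices
        # shoelace area to detect degenerate polygons
        area = 0.5 * abs(np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]))
        if area == 0:
            logger.warning("skipping zero-area polygon of class %s", lb.class_name)
            continue
        x0 = max(int(np.floor(v[:, 0].min())), 0)
        x1 = min(int(np.ceil(v[:, 0].max())), w)
        y0 = max(int(np.floor(v[:, 1].min())), 0)
        y1 = min(int(np.ceil(v[:, 1].max())), h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        hit = _points_in_polygon(xs + 0.5, ys + 0.5, v)
        sub = mask[y0:y1, x0:x1]
        sub[hit] = RASTER_INDEX[lb.class_name]
    return mask


# ---------------------------------------------------------------------------
# YOLO-format boxes
# ---------------------------------------------------------------------------

def read_yolo_boxes(path: str | Path, image_size: tuple[int, int]) -> list[BoundingBox]:
    """Read ``class cx cy w h`` lines with [0,1]-normalized coordinates."""
    h, w = image_size
    boxes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        cls = int(parts[0])
        cx, cy, bw, bh = map(float, parts[1:])
        for name, val in (("cx", cx), ("cy", cy), ("w", bw), ("h", bh)):
            if not 0.0 <= val <= 1.0:
                raise AnnotationError(f"{path}:{ln}: {name}={val} outside [0,1]")
        boxes.append(
            BoundingBox(
                cls,
                (cx - bw / 2) * w,
                (cy - bh / 2) * h,
                (cx + bw / 2) * w,
                (cy + bh / 2) * h,
            )
        )
    return boxes


def write_yolo_boxes(boxes: list[BoundingBox], path: str | Path,
                     image_size: tuple[int, int]) -> None:
    h, w = image_size
    lines = []
    for b in boxes:
        cx = (b.x_min + b.x_max) / 2 / w
        cy = (b.y_min + b.y_max) / 2 / h
        lines.append(
            f"{b.class_id} {cx:.6f} {cy:.6f} {b.width / w:.6f} {b.height / h:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Specimen-level split
# ---------------------------------------------------------------------------

def split_dataset(specimen_ids: list[int], seed: int = 0,
                  ratios: tuple[float, float, float] = (8, 1, 1)) -> Split:
    """Shuffle specimen ids and partition them train/val/test.

    Train size is the nearest integer to ``ratios[0]/sum(ratios) * N``;
    the remainder is split evenly between validation and test, with
    validation receiving the extra item when the remainder is odd.
    """
    ids = list(specimen_ids)
    if len(ids) != len(set(ids)):
        raise AnnotationError("specimen ids must be unique")
    if len(ids) < 3:
        raise AnnotationError("need at least 3 specimens to form 3 partitions")
    frac = ratios[0] / sum(ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(frac * len(ids) + 0.5))
    n_train = min(max(n_train, 1), len(ids) - 2)
    rem = len(ids) - n_train
    n_val = (rem + 1) // 2
    return Split(shuffled[:n_train], shuffled[n_train:n_train + n_val],
                 shuffled[n_train + n_val:])


def save_split(split: Split, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "train": [int(i) for i in split.train_ids],
        "val": [int(i) for i in split.val_ids],
        "test": [int(i) for i in split.test_ids],
    }, indent=1))


def load_split(path: str | Path) -> Split:
    doc = json.loads(Path(path).read_text())
    return Split(doc["train"], doc["val"], doc["test"])


# ---------------------------------------------------------------------------
# Mask PNG I/O (single-channel indexed)
# ---------------------------------------------------------------------------

def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    im = PILImage.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for rgb in MASK_PALETTE:
        palette.extend(rgb)
    palette.extend([0] * (768 - len(palette)))
    im.putpalette(palette)
    im.save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    im = PILImage.open(path)
    if im.mode not in ("P", "L"):
        raise AnnotationError(f"{path}: expected indexed or grayscale PNG, got {im.mode}")
    return np.asarray(im, dtype=np.uint8)
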