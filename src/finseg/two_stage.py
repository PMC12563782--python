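"""Detect-then-segment fusion for surface defects.

The detector proposes coarse defect boxes; each box is padded for
context, cropped, segmented at pixel level by the crop U-Net, and the
crop mask is pasted back into a full-frame defect raster.  Only the
proposed regions are ever segmented, which is what makes the pipeline
faster than running the dense segmenter over the whole frame when
defects cover a small fraction of it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from PIL import Image as PILImage

from .annotations import BoundingBox
from .cbam_unet import UNet, predict_mask
from .p2_yolo import P2Detector, detect
from .preprocess import resize_bicubic

__all__ = ["CropTransform", "DefectSegmentation", "TwoStageConfig",
           "crop_regions", "paste_masks", "run_two_stage"]


@dataclass(frozen=True)
class CropTransform:
    """Geometry linking a padded source box to the segmenter's input."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    crop_size: int
    confidence: float = 1.0

    @property
    def scale_x(self) -> float:
        return self.crop_size / (self.x_max - self.x_min)

    @property
    def scale_y(self) -> float:
        return self.crop_size / (self.y_max - self.y_min)


@dataclass
class DefectSegmentation:
    mask: np.ndarray                    # H x W uint8: 0 none, 1 fat, 2 bruise
    boxes: list[BoundingBox]            # contributing (padded-source) boxes


@dataclass(frozen=True)
class TwoStageConfig:
    pad_fraction: float = 0.15   # context added per side before cropping
    crop_size: int = 64          # segmenter input (divisible by 2^depth)
    conf_threshold: float | None = None   # falls back to the detector's


def crop_regions(img: np.ndarray, boxes: list[BoundingBox],
                 pad_fraction: float = 0.15,
                 crop_size: int = 64) -> list[tuple[np.ndarray, CropTransform]]:
    """Pad each box per side by ``pad_fraction`` of its size, clip to the
    frame, crop, and resize (bicubic) to the segmenter input size."""
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be >= 0")
    h, w = img.shape[:2]
    out = []
    for b in boxes:
        px = pad_fraction * b.width
        py = pad_fraction * b.height
        x0 = int(np.floor(max(b.x_min - px, 0)))
        y0 = int(np.floor(max(b.y_min - py, 0)))
        x1 = int(np.ceil(min(b.x_max + px, w)))
        y1 = int(np.ceil(min(b.y_max + py, h)))
        if x1 - x0 < 1 or y1 - y0 < 1:
            continue
        crop = img[y0:y1, x0:x1]
        if crop.shape[:2] != (crop_size, crop_size):
            crop = resize_bicubic(crop, (crop_size, crop_size))
        out.append((crop, CropTransform(x0, y0, x1, y1, crop_size, b.confidence)))
    return out


def paste_masks(crop_masks: list[np.ndarray], transforms: list[CropTransform],
                full_size: tuple[int, int]) -> DefectSegmentation:
    """Resize crop masks back (nearest-neighbour) and write them into a
    full-frame raster.  Where padded boxes overlap with different
    nonzero labels, the higher-confidence box wins; background never
    overwrites a nonzero label."""
    if len(crop_masks) != len(transforms):
        raise ValueError("one mask per transform required")
    h, w = full_size
    full = np.zeros((h, w), dtype=np.uint8)
    conf = np.full((h, w), -1.0)
    boxes = []
    for mask, tr in zip(crop_masks, transforms):
        if tr.x_max > w or tr.y_max > h or tr.x_min < 0 or tr.y_min < 0:
            raise ValueError(f"transform {tr} outside frame {full_size}")
        bw, bh = tr.x_max - tr.x_min, tr.y_max - tr.y_min
        if mask.shape != (bh, bw):
            back = PILImage.fromarray(mask.astype(np.uint8)).resize(
                (bw, bh), PILImage.NEAREST)
            mask = np.asarray(back)
        region_m = full[tr.y_min:tr.y_max, tr.x_min:tr.x_max]
        region_c = conf[tr.y_min:tr.y_max, tr.x_min:tr.x_max]
        write = (mask > 0) & ((region_m == 0) | (tr.confidence > region_c))
        region_m[write] = mask[write]
        region_c[write] = tr.confidence
        boxes.append(BoundingBox(0, tr.x_min, tr.y_min, tr.x_max, tr.y_max,
                                 tr.confidence))
    return DefectSegmentation(full, boxes)


def run_two_stage(img: np.ndarray, detector: P2Detector, segmenter: UNet,
                  cfg: TwoStageConfig = TwoStageConfig(),
                  timings: dict | None = None) -> DefectSegmentation:
    """Full pipeline: detect, pad+crop, segment each crop, paste back.

    An image with no detections yields an all-zero mask.  When a dict is
    passed as ``timings`` it receives per-stage wall times in seconds
    under ``detect`` / ``segment`` / ``paste``.
    """
    t0 = time.perf_counter()
    boxes = detect(detector, img, conf_threshold=cfg.conf_threshold)
    t1 = time.perf_counter()
    crops = crop_regions(img, boxes, cfg.pad_fraction, cfg.crop_size)
    masks = [predict_mask(segmenter, crop)[0] for crop, _ in crops]
    t2 = time.perf_counter()
    seg = paste_masks(masks, [tr for _, tr in crops], img.shape[:2])
    t3 = time.perf_counter()
    if timings is not None:
        timings.update({"detect": t1 - t0, "segment": t2 - t1, "paste": t3 - t2})
    return seg
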