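"""Image conditioning: bicubic resize, gamma, CLAHE, and online augmentation.

All functions take and return ``H x W x 3`` uint8 RGB arrays.  Geometry
applied during augmentation is shared exactly between the image, its
label mask (nearest-neighbour) and its boxes (corner transform followed
by re-tightening), so annotations never drift from the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure

from .annotations import BoundingBox

__all__ = ["AugmentPolicy", "resize_bicubic", "gamma_correct", "clahe", "augment"]


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    return img


def resize_bicubic(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Resize to ``(height, width)`` with bicubic interpolation."""
    img = _check_image(img)
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"invalid target size {target}")
    if (th, tw) == img.shape[:2]:
        return img.copy()
    out = PILImage.fromarray(img).resize((tw, th), PILImage.BICUBIC)
    return np.asarray(out)


def gamma_correct(img: np.ndarray, gamma: float,
                  region_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-channel power-law mapping ``v' = round(255 (v/255)^gamma)``.

    With ``region_mask`` given, only pixels where the mask is nonzero
    are corrected (for locally reflective or dark areas); the default is
    a global correction.
    """
    img = _check_image(img)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    lut = np.round(255.0 * (np.arange(256) / 255.0) ** gamma).astype(np.uint8)
    out = lut[img]
    if region_mask is not None:
        out = np.where(np.asarray(region_mask, bool)[..., None], out, img)
    return out


def clahe(img: np.ndarray, clip_limit: float = 2.0,
          tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on luminance.

    The image is converted to CIELAB, the L channel equalized tile-wise,
    and the result converted back, so chroma (the colour cue separating
    fat from bruise from tissue) is untouched.  ``clip_limit`` follows
    the common convention of multiples of the uniform histogram bin
    height.  A constant image is returned unchanged (its histogram sits
    in one bin; clipping redistributes to an identity mapping).
    """
    img = _check_image(img)
    h, w = img.shape[:2]
    ty, tx = tiles
    if ty < 1 or tx < 1 or clip_limit <= 0:
        raise ValueError("clip_limit and tile counts must be positive")
    if ty > h or tx > w:
        raise ValueError(f"tile grid {tiles} exceeds image size {(h, w)}")
    lab = skcolor.rgb2lab(img.astype(np.float64) / 255.0)
    lum = lab[..., 0] / 100.0
    if lum.max() - lum.min() < 1e-9:
        return img.copy()
    kernel = (max(1, h // ty), max(1, w // tx))
    lab[..., 0] = exposure.equalize_adapthist(
        np.clip(lum, 0, 1), kernel_size=kernel, clip_limit=clip_limit / 256.0
    ) * 100.0
    out = skcolor.lab2rgb(lab)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class AugmentPolicy:
    """Online augmentation ranges (uniform draws within each range)."""

    brightness_delta: float = 0.20
    contrast_delta: float = 0.20
    hue_delta: float = 0.10
    saturation_delta: float = 0.20
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5

    def __post_init__(self):
        if min(self.brightness_delta, self.contrast_delta, self.hue_delta,
               self.saturation_delta, self.rotation_deg) < 0:
            raise ValueError("augmentation deltas must be >= 0")
        if not self.scale_range[0] <= self.scale_range[1]:
            raise ValueError("scale_range must be (low, high) with low <= high")

    @classmethod
    def null(cls) -> "AugmentPolicy":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, (1.0, 1.0), 0.0)


def _affine_matrix(angle_deg: float, scale: float, flip: bool,
                   w: int, h: int) -> np.ndarray:
    """Forward 3x3 matrix mapping input (x, y, 1) to output coordinates:
    flip, then rotate+scale about the frame centre."""
    cx, cy = w / 2.0, h / 2.0
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t) * scale, np.sin(t) * scale
    rot = np.array([[c, -s, cx - c * cx + s * cy],
                    [s, c, cy - s * cx - c * cy],
                    [0, 0, 1.0]])
    if flip:
        fl = np.array([[-1.0, 0, w], [0, 1.0, 0], [0, 0, 1.0]])
        return rot @ fl
    return rot


def _warp(arr: np.ndarray, fwd: np.ndarray, order: int) -> np.ndarray:
    """Apply forward affine via its inverse (scipy maps output->input).

    Works in the pixel-centre frame: array index i corresponds to
    coordinate i + 0.5.
    """
    inv = np.linalg.inv(fwd)
    # index -> coordinate offset: x = j + 0.5 -> input index = inv@x - 0.5
    mat = inv[:2, :2][::-1, ::-1]  # (row, col) convention
    off = (inv[:2, 2] + inv[:2, :2] @ np.array([0.5, 0.5]) - 0.5)[::-1]
    if arr.ndim == 3:
        chans = [ndimage.affine_transform(arr[..., c].astype(np.float32), mat, off,
                                          order=order, mode="constant", cval=0.0)
                 for c in range(arr.shape[2])]
        out = np.stack(chans, axis=-1)
        return np.clip(np.round(out), 0, 255).astype(arr.dtype)
    return ndimage.affine_transform(arr, mat, off, order=order, mode="constant",
                                    cval=0, output=arr.dtype)


def _transform_boxes(boxes: Sequence[BoundingBox], fwd: np.ndarray,
                     w: int, h: int) -> list[BoundingBox]:
    out = []
    for b in boxes:
        corners = np.array([[b.x_min, b.y_min, 1], [b.x_max, b.y_min, 1],
                            [b.x_min, b.y_max, 1], [b.x_max, b.y_max, 1]]).T
        tc = fwd @ corners
        x0, y0 = tc[0].min(), tc[1].min()
        x1, y1 = tc[0].max(), tc[1].max()
        x0, x1 = np.clip([x0, x1], 0, w)
        y0, y1 = np.clip([y0, y1], 0, h)
        if (x1 - x0) * (y1 - y0) < 1.0:
            continue
        out.append(BoundingBox(b.class_id, x0, y0, x1, y1, b.confidence))
    return out


def augment(img: np.ndarray, part_mask: np.ndarray | None,
            boxes: Sequence[BoundingBox] | None, policy: AugmentPolicy,
            seed: int):
    """One random draw of the policy applied consistently to all inputs.

    Returns the ``(image, mask, boxes)`` triple; mask and boxes come
    back as ``None`` when not supplied.  Photometric jitter touches only
    the image; the geometric transform is shared.
    """
    img = _check_image(img)
    h, w = img.shape[:2]
    if part_mask is not None and part_mask.shape != (h, w):
        raise ValueError(f"mask shape {part_mask.shape} != image {(h, w)}")
    rng = np.random.default_rng(seed)

    db = rng.uniform(-policy.brightness_delta, policy.brightness_delta)
    dc = rng.uniform(-policy.contrast_delta, policy.contrast_delta)
    dh = rng.uniform(-policy.hue_delta, policy.hue_delta)
    ds = rng.uniform(-policy.saturation_delta, policy.saturation_delta)
    ang = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    scale = rng.uniform(*policy.scale_range)
    flip = bool(rng.random() < policy.hflip_prob)

    out = img.astype(np.float32)
    if db != 0.0:
        out = out * (1.0 + db)
    if dc != 0.0:
        m = out.mean()
        out = (out - m) * (1.0 + dc) + m
    if dh != 0.0 or ds != 0.0:
        hsv = skcolor.rgb2hsv(np.clip(out, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + ds), 0, 1)
        out = skcolor.hsv2rgb(hsv) * 255.0
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)

    new_mask = None if part_mask is None else part_mask
    new_boxes = None if boxes is None else list(boxes)
    if ang != 0.0 or scale != 1.0 or flip:
        fwd = _affine_matrix(ang, scale, flip, w, h)
        out = _warp(out, fwd, order=1)
        if part_mask is not None:
            new_mask = _warp(part_mask, fwd, order=0)
        if boxes is not None:
            new_boxes = _transform_boxes(boxes, fwd, w, h)
    elif part_mask is not None:
        new_mask = part_mask.copy()
    return out, new_mask, new_boxes
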