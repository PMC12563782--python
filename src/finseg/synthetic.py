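"""Synthetic fillet imagery with pixel-perfect part masks and defect labels.

The generator emulates the situation the processing-line models face: an
elongated, roughly elliptical skinned fillet on a darker conveyor-like
background, three longitudinal anatomical bands (belly, loin, back) that
differ in colour statistics and in low-frequency myotome stripe texture,
and a handful of small defect blobs of two classes — pale fat deposits
and dark-red bruises — scattered over the tissue.  Every sample carries
its ground truth (part mask, defect mask, tight defect boxes), so the
segmentation and detection models can be trained and scored without any
external data.

Band boundaries are placed by inverting the ellipse-area CDF so that the
requested ``band_fractions`` are fractions of *body pixels*, not of body
height; a straight height split would systematically starve the outer
bands on an elliptical body.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .annotations import BoundingBox, save_mask_png, write_yolo_boxes

__all__ = ["SyntheticSpec", "SyntheticSample", "generate_sample", "generate_dataset",
           "save_dataset"]


@dataclass(frozen=True)
class BandTexture:
    """Per-band colour and stripe statistics."""

    color_mean: tuple[float, float, float]
    color_sd: float
    stripe_freq: float      # stripe cycles along the body's major axis
    stripe_amp: float       # peak luminance modulation, intensity levels


@dataclass(frozen=True)
class SyntheticSpec:
    image_size: int = 512
    body_axis_ratio: float = 2.6          # major/minor semi-axis ratio
    band_fractions: tuple[float, float, float] = (0.30, 0.40, 0.30)
    # belly: pale pink with dense fine fat striping; loin: saturated orange;
    # back: darker red-brown with sparse coarse stripes
    textures: tuple[BandTexture, BandTexture, BandTexture] = (
        BandTexture((244, 186, 158), 6.0, 22.0, 16.0),
        BandTexture((236, 128, 72), 6.0, 12.0, 10.0),
        BandTexture((182, 84, 52), 6.0, 7.0, 12.0),
    )
    defect_count_range: tuple[int, int] = (1, 3)   # per class, inclusive
    defect_radius_range: tuple[float, float] = (2.0, 12.0)  # px at 512
    fat_color: tuple[float, float, float] = (238, 232, 210)
    bruise_color: tuple[float, float, float] = (110, 28, 34)
    defect_color_sd: float = 5.0
    background_color: tuple[float, float, float] = (74, 92, 108)
    illumination_gradient: float = 0.12   # max relative brightness slope
    noise_sd: float = 4.0
    rotation_deg: float = 15.0            # body pose jitter
    translation_frac: float = 0.05

    def validate(self) -> None:
        if abs(sum(self.band_fractions) - 1.0) > 1e-9:
            raise ValueError(f"band_fractions sum to {sum(self.band_fractions)}, not 1")
        if any(f <= 0 for f in self.band_fractions):
            raise ValueError("band_fractions must be positive")
        minor = 0.42 * self.image_size / self.body_axis_ratio
        if self.defect_radius_range[1] >= minor / 4:
            raise ValueError(
                f"max defect radius {self.defect_radius_range[1]} must be < "
                f"body minor axis / 4 = {minor / 4:.1f}"
            )
        for tex in self.textures:
            if not all(0 <= c <= 255 for c in tex.color_mean):
                raise ValueError("band colour means must lie in [0,255]")
        for col in (self.fat_color, self.bruise_color, self.background_color):
            if not all(0 <= c <= 255 for c in col):
                raise ValueError("colour means must lie in [0,255]")
        if self.defect_count_range[0] > self.defect_count_range[1] or self.defect_count_range[0] < 0:
            raise ValueError("invalid defect_count_range")


@dataclass
class SyntheticSample:
    image: np.ndarray        # H x W x 3 uint8
    part_mask: np.ndarray    # H x W uint8: 0 bg, 1 belly, 2 loin, 3 back
    defect_mask: np.ndarray  # H x W uint8: 0 none, 1 fat, 2 bruise
    defect_boxes: list[BoundingBox]   # class_id 0 = fat, 1 = bruise
    specimen_id: int = 0


def _ellipse_area_cuts(fractions: tuple[float, ...]) -> list[float]:
    """Normalized minor-axis offsets z in [-1,1] cutting an ellipse into
    bands holding the requested area fractions."""

    def cdf(z: float) -> float:
        return (z * np.sqrt(1 - z * z) + np.arcsin(z)) / np.pi + 0.5

    cuts = []
    acc = 0.0
    for f in fractions[:-1]:
        acc += f
        cuts.append(brentq(lambda z: cdf(z) - acc, -1 + 1e-12, 1 - 1e-12))
    return cuts


def _paint_blob(rng: np.random.Generator, mask: np.ndarray, image: np.ndarray,
                cx: float, cy: float, radius: float, label: int,
                color: tuple[float, float, float], color_sd: float,
                body: np.ndarray) -> None:
    """Rasterize one irregular blob (radius modulated by low harmonics)."""
    h, w = mask.shape
    phase = rng.uniform(0, 2 * np.pi, size=2)
    amp = rng.uniform(0.08, 0.25, size=2)
    r_out = radius * (1 + amp.sum())
    x0, x1 = max(int(cx - r_out - 1), 0), min(int(cx + r_out + 2), w)
    y0, y1 = max(int(cy - r_out - 1), 0), min(int(cy + r_out + 2), h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs + 0.5 - cx, ys + 0.5 - cy
    ang = np.arctan2(dy, dx)
    rr = radius * (1 + amp[0] * np.sin(2 * ang + phase[0]) + amp[1] * np.sin(3 * ang + phase[1]))
    hit = (dx * dx + dy * dy <= rr * rr) & body[y0:y1, x0:x1]
    mask[y0:y1, x0:x1][hit] = label
    patch = image[y0:y1, x0:x1]
    col = np.asarray(color) + rng.normal(0, color_sd, size=(hit.sum(), 3))
    patch[hit] = col


def generate_sample(spec: SyntheticSpec, seed: int) -> SyntheticSample:
    """Render one fillet image with its masks and tight defect boxes.

    Deterministic for a fixed ``(spec, seed)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    s = spec.image_size
    ys, xs = np.mgrid[0:s, 0:s].astype(np.float64) + 0.5

    # body pose: rotation and translation jitter around the frame centre
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    cx = s / 2 + rng.uniform(-1, 1) * spec.translation_frac * s
    cy = s / 2 + rng.uniform(-1, 1) * spec.translation_frac * s
    a = 0.42 * s                      # semi-major axis
    b = a / spec.body_axis_ratio      # semi-minor axis
    u = np.cos(theta) * (xs - cx) + np.sin(theta) * (ys - cy)   # along major
    v = -np.sin(theta) * (xs - cx) + np.cos(theta) * (ys - cy)  # along minor
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    # belly -> loin -> back bands across the minor axis, area-matched
    cuts = _ellipse_area_cuts(spec.band_fractions)
    part = np.zeros((s, s), dtype=np.uint8)
    z = v / b
    band = np.ones((s, s), dtype=np.uint8)
    for c in cuts:
        band += (z > c).astype(np.uint8)
    part[body] = band[body]

    # base colouring with myotome stripes
    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = spec.background_color
    for i, tex in enumerate(spec.textures, start=1):
        sel = part == i
        phase = rng.uniform(0, 2 * np.pi)
        stripe = tex.stripe_amp * np.sin(2 * np.pi * tex.stripe_freq * (u / (2 * a)) + phase)
        base = np.asarray(tex.color_mean)[None, :] + stripe[sel, None]
        base += rng.normal(0, tex.color_sd, size=(sel.sum(), 3))
        img[sel] = base

    # defects: rejection-sampled fully inside the body
    defect = np.zeros((s, s), dtype=np.uint8)
    edt = ndimage.distance_transform_edt(body)
    for label, color in ((1, spec.fat_color), (2, spec.bruise_color)):
        lo, hi = spec.defect_count_range
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            radius = rng.uniform(*spec.defect_radius_range)
            cand = np.argwhere(edt > radius * 1.35 + 1.0)
            if len(cand) == 0:
                continue
            py, px = cand[rng.integers(len(cand))]
            _paint_blob(rng, defect, img, px + 0.5, py + 0.5, radius, label,
                        color, spec.defect_color_sd, body)

    # illumination gradient and sensor noise
    direction = rng.uniform(0, 2 * np.pi)
    ramp = ((xs / s - 0.5) * np.cos(direction) + (ys / s - 0.5) * np.sin(direction))
    img *= (1.0 + spec.illumination_gradient * ramp)[..., None]
    img += rng.normal(0, spec.noise_sd, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    boxes = defect_boxes_from_mask(defect)
    return SyntheticSample(image, part, defect, boxes)


def defect_boxes_from_mask(defect_mask: np.ndarray) -> list[BoundingBox]:
    """Tight half-open boxes of each connected defect blob (class-wise)."""
    boxes = []
    for label in (1, 2):
        comp, n = ndimage.label(defect_mask == label)
        for sl in ndimage.find_objects(comp):
            if sl is None:
                continue
            ysl, xsl = sl
            boxes.append(BoundingBox(label - 1, xsl.start, ysl.start,
                                     xsl.stop, ysl.stop))
    return boxes


def generate_dataset(n: int, spec: SyntheticSpec | None = None,
                     seed: int = 0) -> list[SyntheticSample]:
    """Generate ``n`` samples with specimen ids ``0..n-1``.

    Per-sample seeds are spawned from the master seed, so any prefix of
    the dataset is reproducible independently of ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SyntheticSpec()
    samples = []
    for i in range(n):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        sample_seed = int(child.generate_state(1)[0]) % (2**31)
        sample = generate_sample(spec, sample_seed)
        sample.specimen_id = i
        samples.append(sample)
    return samples


def save_dataset(samples: list[SyntheticSample], out_dir: str | Path) -> None:
    """Write images (PNG), part masks (indexed PNG) and defect boxes (YOLO)."""
    from PIL import Image as PILImage

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "part_masks").mkdir(exist_ok=True)
    (out / "defect_masks").mkdir(exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    for sm in samples:
        stem = f"{sm.specimen_id:05d}"
        PILImage.fromarray(sm.image).save(out / "images" / f"{stem}.png")
        save_mask_png(sm.part_mask, out / "part_masks" / f"{stem}.png")
        save_mask_png(sm.defect_mask, out / "defect_masks" / f"{stem}.png")
        write_yolo_boxes(sm.defect_boxes, out / "labels" / f"{stem}.txt",
                         sm.image.shape[:2])
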