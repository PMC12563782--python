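"""Single-stage defect detector with a high-resolution P2 head.

A CSP-style backbone (Focus space-to-depth stem, C3 cross-stage partial
blocks, SPPF pooling) feeds an FPN/PAN neck.  Besides the usual P3/P4/P5
heads (strides 8/16/32), the top-down path continues one level further
and its upsampled features are concatenated with the backbone's stride-4
map, giving a P2 head on a grid four times finer than P5 — at 640-pixel
input the four heads see 160/80/40/20 cells.  The extra resolution is
what makes defects only a few pixels wide resolvable at all.

Box decoding follows the v5-style parameterisation: per anchor cell,
``center = (cell + 2 sigmoid(t_xy) - 0.5) * stride`` and
``size = anchor * (2 sigmoid(t_wh))^2``, with confidence
``sigmoid(obj) * sigmoid(cls)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concatenate
from .annotations import BoundingBox

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "focus_slice",
    "unfocus_slice",
    "P2Detector",
    "build_detector",
    "decode_predictions",
    "nms",
    "mosaic_augment",
    "kmeans_anchors",
    "DetTrainConfig",
    "train_detector",
    "evaluate_detector",
    "detect",
    "save_detector",
    "load_detector",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_ANCHORS_640 = (
    ((4, 5), (8, 10), (13, 16)),          # P2 / stride 4
    ((19, 24), (28, 35), (41, 52)),       # P3 / stride 8
    ((60, 75), (88, 110), (128, 160)),    # P4 / stride 16
    ((185, 230), (270, 340), (400, 500)),  # P5 / stride 32
)


@dataclass(frozen=True)
class DetectorConfig:
    input_size: int = 640
    n_classes: int = 2                      # fat, bruise
    strides: tuple[int, ...] = (4, 8, 16, 32)
    anchors: tuple | None = None            # 3 (w,h) pairs per active level
    width_multiple: float = 0.50
    depth_multiple: float = 0.33
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    use_p2: bool = True
    anchor_t: float = 4.0                   # anchor-match wh ratio bound
    # "ratio": every anchor within the wh-ratio bound trains, but only at
    # levels fine enough to localize the box (stride <= box size / 0.75);
    # "best": each box trains only its single best-fitting anchor
    anchor_match: str = "ratio"
    min_size_per_stride: float = 0.75       # box must span this many cells

    def __post_init__(self):
        if self.input_size % max(self.strides):
            raise ValueError("input_size must be divisible by the max stride")

    @property
    def active_strides(self) -> tuple[int, ...]:
        return self.strides if self.use_p2 else self.strides[1:]

    @property
    def n_levels(self) -> int:
        return len(self.active_strides)

    def level_anchors(self) -> np.ndarray:
        """(L, 3, 2) anchor sizes in input pixels for the active levels."""
        if self.anchors is not None:
            a = np.asarray(self.anchors, dtype=float)
        else:
            scale = self.input_size / 640.0
            full = np.asarray(_DEFAULT_ANCHORS_640, dtype=float) * scale
            a = full if self.use_p2 else full[1:]
        if a.shape != (self.n_levels, 3, 2):
            raise ValueError(f"anchors must have shape ({self.n_levels},3,2), got {a.shape}")
        return a

    @property
    def base_channels(self) -> int:
        return max(4, int(round(64 * self.width_multiple / 4)) * 4)

    @property
    def block_repeats(self) -> int:
        return max(1, round(3 * self.depth_multiple))


# ---------------------------------------------------------------------------
# Focus slicing
# ---------------------------------------------------------------------------

def focus_slice(x):
    """Space-to-depth: (…,C,S,S) -> (…,4C,S/2,S/2) by pixel parity.

    Accepts a numpy array or a Tensor; the four parity subimages are
    concatenated along channels in the order (even,even), (odd,even),
    (even,odd), (odd,odd) of (row, col).
    """
    if x.shape[-1] % 2 or x.shape[-2] % 2:
        raise ValueError(f"spatial dims must be even, got {x.shape[-2:]}")
    if isinstance(x, Tensor):
        parts = [x[..., ::2, ::2], x[..., 1::2, ::2], x[..., ::2, 1::2],
                 x[..., 1::2, 1::2]]
        return concatenate(parts, axis=-3 if x.ndim == 3 else 1)
    parts = [x[..., ::2, ::2], x[..., 1::2, ::2], x[..., ::2, 1::2], x[..., 1::2, 1::2]]
    return np.concatenate(parts, axis=-3)


def unfocus_slice(y: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`focus_slice` for numpy arrays."""
    c4 = y.shape[-3]
    if c4 % 4:
        raise ValueError("channel count must be a multiple of 4")
    c = c4 // 4
    h, w = y.shape[-2:]
    out = np.empty(y.shape[:-3] + (c, 2 * h, 2 * w), dtype=y.dtype)
    out[..., ::2, ::2] = y[..., 0 * c:1 * c, :, :]
    out[..., 1::2, ::2] = y[..., 1 * c:2 * c, :, :]
    out[..., ::2, 1::2] = y[..., 2 * c:3 * c, :, :]
    out[..., 1::2, 1::2] = y[..., 3 * c:4 * c, :, :]
    return out


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class ConvBN(nn.Module):
    def __init__(self, cin: int, cout: int, k: int = 1, s: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=s, padding=k // 2, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    def __init__(self, cin: int, cout: int, shortcut: bool = True):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBN(cin, c_, 1)
        self.cv2 = ConvBN(c_, cout, 3)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """Cross-stage partial block: a bottleneck stack on half the width,
    the other half passed through, fused by a 1x1 convolution."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBN(cin, c_, 1)
        self.cv2 = ConvBN(cin, c_, 1)
        self.m = nn.Sequential(*[Bottleneck(c_, c_, shortcut) for _ in range(n)])
        self.cv3 = ConvBN(2 * c_, cout, 1)

    def forward(self, x):
        return self.cv3(concatenate([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class SPPF(nn.Module):
    def __init__(self, cin: int, cout: int, k: int = 5):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBN(cin, c_, 1)
        self.cv2 = ConvBN(c_ * 4, cout, 1)
        self.pool = nn.MaxPool2d(k, stride=1, padding=k // 2)

    def forward(self, x):
        x = self.cv1(x)
        y1 = self.pool(x)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concatenate([x, y1, y2, y3], axis=1))


class P2Detector(nn.Module):
    """Backbone + FPN/PAN neck + one 1x1 detection head per active level."""

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.base_channels
        n = cfg.block_repeats
        no = 3 * (5 + cfg.n_classes)
        # backbone
        self.stem = ConvBN(12, c, 3)                     # after Focus: stride 2
        self.down2 = ConvBN(c, 2 * c, 3, 2)              # stride 4
        self.c3_2 = C3(2 * c, 2 * c, n)
        self.down3 = ConvBN(2 * c, 4 * c, 3, 2)          # stride 8
        self.c3_3 = C3(4 * c, 4 * c, n)
        self.down4 = ConvBN(4 * c, 8 * c, 3, 2)          # stride 16
        self.c3_4 = C3(8 * c, 8 * c, n)
        self.down5 = ConvBN(8 * c, 16 * c, 3, 2)         # stride 32
        self.c3_5 = C3(16 * c, 16 * c, n)
        self.sppf = SPPF(16 * c, 16 * c)
        # FPN (top-down)
        self.lat5 = ConvBN(16 * c, 8 * c, 1)
        self.fpn4 = C3(16 * c, 8 * c, n, shortcut=False)
        self.lat4 = ConvBN(8 * c, 4 * c, 1)
        self.fpn3 = C3(8 * c, 4 * c, n, shortcut=False)
        if cfg.use_p2:
            self.lat3 = ConvBN(4 * c, 2 * c, 1)
            self.fpn2 = C3(4 * c, 2 * c, n, shortcut=False)
        # PAN (bottom-up)
        if cfg.use_p2:
            self.pan_d2 = ConvBN(2 * c, 2 * c, 3, 2)
            self.pan3 = C3(4 * c, 4 * c, n, shortcut=False)
        self.pan_d3 = ConvBN(4 * c, 4 * c, 3, 2)
        self.pan4 = C3(8 * c, 8 * c, n, shortcut=False)
        self.pan_d4 = ConvBN(8 * c, 8 * c, 3, 2)
        self.pan5 = C3(16 * c, 16 * c, n, shortcut=False)
        # heads (finest level first, matching cfg.active_strides)
        widths = ([2 * c, 4 * c, 8 * c, 16 * c] if cfg.use_p2
                  else [4 * c, 8 * c, 16 * c])
        self.heads = [nn.Conv2d(w, no, 1) for w in widths]
        for head in self.heads:
            bias = head.bias.data.reshape(3, 5 + cfg.n_classes)
            bias[:, 4] = -4.6   # objectness prior ~1%
            bias[:, 5:] = -2.0
            head.bias.data = bias.reshape(-1)

    def forward(self, x: Tensor) -> list[Tensor]:
        size = self.cfg.input_size
        if x.shape[-1] != size or x.shape[-2] != size:
            raise ValueError(f"expected {size}x{size} input, got {x.shape[-2:]}")
        x = self.stem(focus_slice(x))
        b2 = self.c3_2(self.down2(x))        # stride 4
        b3 = self.c3_3(self.down3(b2))       # stride 8
        b4 = self.c3_4(self.down4(b3))       # stride 16
        b5 = self.sppf(self.c3_5(self.down5(b4)))  # stride 32

        p5 = self.lat5(b5)
        f4 = self.fpn4(concatenate([F.upsample_nearest2d(p5), b4], axis=1))
        p4 = self.lat4(f4)
        f3 = self.fpn3(concatenate([F.upsample_nearest2d(p4), b3], axis=1))
        if self.cfg.use_p2:
            p3 = self.lat3(f3)
            # top-down P2 features fused with the backbone stride-4 map
            f2 = self.fpn2(concatenate([F.upsample_nearest2d(p3), b2], axis=1))
            g3 = self.pan3(concatenate([self.pan_d2(f2), p3], axis=1))
            g4 = self.pan4(concatenate([self.pan_d3(g3), p4], axis=1))
            g5 = self.pan5(concatenate([self.pan_d4(g4), p5], axis=1))
            feats = [f2, g3, g4, g5]
        else:
            g4 = self.pan4(concatenate([self.pan_d3(f3), p4], axis=1))
            g5 = self.pan5(concatenate([self.pan_d4(g4), p5], axis=1))
            feats = [f3, g4, g5]
        out = []
        for head, feat, stride in zip(self.heads, feats, self.cfg.active_strides):
            raw = head(feat)
            expected = size // stride
            assert raw.shape[-1] == expected and raw.shape[-2] == expected, \
                f"grid {raw.shape[-2:]} != input/stride {expected}"
            out.append(raw)
        return out


def build_detector(cfg: DetectorConfig, seed: int | None = None) -> P2Detector:
    if seed is not None:
        nn.seed_init(seed)
    return P2Detector(cfg)


# ---------------------------------------------------------------------------
# Decoding and NMS
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_predictions(raw: list[np.ndarray], cfg: DetectorConfig,
                       conf_threshold: float | None = None,
                       anchors: np.ndarray | None = None,
                       max_det: int = 300) -> list[list[BoundingBox]]:
    """Decode per-level grids into boxes per image (before NMS).

    At most ``max_det`` highest-confidence candidates survive per image
    (set ``max_det=0`` to disable the cap).
    """
    thr = cfg.conf_threshold if conf_threshold is None else conf_threshold
    if anchors is None:
        anchors = cfg.level_anchors()
    n_img = raw[0].shape[0]
    size = cfg.input_size
    per_image = [[] for _ in range(n_img)]
    for lvl, (grid, stride) in enumerate(zip(raw, cfg.active_strides)):
        n, _, h, w = grid.shape
        p = grid.reshape(n, 3, 5 + cfg.n_classes, h, w)
        s = _sigmoid(p)
        gy, gx = np.mgrid[0:h, 0:w]
        cx = (gx[None, None] + 2 * s[:, :, 0] - 0.5) * stride
        cy = (gy[None, None] + 2 * s[:, :, 1] - 0.5) * stride
        bw = anchors[lvl, :, 0][None, :, None, None] * (2 * s[:, :, 2]) ** 2
        bh = anchors[lvl, :, 1][None, :, None, None] * (2 * s[:, :, 3]) ** 2
        conf = s[:, :, 4:5] * s[:, :, 5:]          # (n, 3, nc, h, w)
        cls = conf.argmax(axis=2)
        best = conf.max(axis=2)
        # strictly above: a bias-free grid scores exactly sigmoid(0)^2
        ii, aa, yy, xx = np.nonzero(best > thr)
        x0 = np.clip(cx[ii, aa, yy, xx] - bw[ii, aa, yy, xx] / 2, 0, size)
        x1 = np.clip(cx[ii, aa, yy, xx] + bw[ii, aa, yy, xx] / 2, 0, size)
        y0 = np.clip(cy[ii, aa, yy, xx] - bh[ii, aa, yy, xx] / 2, 0, size)
        y1 = np.clip(cy[ii, aa, yy, xx] + bh[ii, aa, yy, xx] / 2, 0, size)
        ok = (x1 - x0 > 1e-3) & (y1 - y0 > 1e-3)
        cand = np.stack([x0, y0, x1, y1, best[ii, aa, yy, xx],
                         cls[ii, aa, yy, xx]], axis=1)[ok]
        for img_idx, row in zip(ii[ok], cand):
            per_image[img_idx].append(row)
    results: list[list[BoundingBox]] = []
    for rows in per_image:
        if not rows:
            results.append([])
            continue
        arr = np.stack(rows)
        if max_det and len(arr) > max_det:
            arr = arr[np.argsort(-arr[:, 4])[:max_det]]
        results.append([
            BoundingBox(int(r[5]), float(r[0]), float(r[1]), float(r[2]),
                        float(r[3]), float(r[4]))
            for r in arr
        ])
    return results


def nms(boxes: list[BoundingBox], iou_threshold: float = 0.45) -> list[BoundingBox]:
    """Class-wise greedy suppression by descending confidence
    (ties broken by earlier list index)."""
    from .metrics import box_iou

    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    keep: list[int] = []
    for i in order:
        bi = boxes[i]
        if all(boxes[j].class_id != bi.class_id
               or box_iou(bi, boxes[j]) < iou_threshold for j in keep):
            keep.append(i)
    return [boxes[i] for i in sorted(keep)]


# ---------------------------------------------------------------------------
# Mosaic augmentation
# ---------------------------------------------------------------------------

def mosaic_augment(samples, out_size: int, seed: int):
    """Splice four (image, boxes) samples into one canvas.

    A random centre point splits the canvas into four quadrants; each
    sample is resized (plain affine scaling) into one quadrant and its
    boxes are transformed, clipped to the canvas, and dropped below
    1 px^2.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic needs exactly 4 samples, got {len(samples)}")
    rng = np.random.default_rng(seed)
    cx = int(rng.uniform(0.25, 0.75) * out_size)
    cy = int(rng.uniform(0.25, 0.75) * out_size)
    quads = [(0, 0, cx, cy), (cx, 0, out_size, cy),
             (0, cy, cx, out_size), (cx, cy, out_size, out_size)]
    canvas = np.zeros((out_size, out_size, 3), dtype=np.uint8)
    out_boxes: list[BoundingBox] = []
    for (x0, y0, x1, y1), (img, boxes) in zip(quads, samples):
        qw, qh = x1 - x0, y1 - y0
        if qw < 1 or qh < 1:
            continue
        h, w = img.shape[:2]
        resized = np.asarray(
            PILImage.fromarray(img).resize((qw, qh), PILImage.BILINEAR)
        )
        canvas[y0:y1, x0:x1] = resized
        sx, sy = qw / w, qh / h
        for b in boxes:
            nx0 = np.clip(b.x_min * sx + x0, x0, x1)
            nx1 = np.clip(b.x_max * sx + x0, x0, x1)
            ny0 = np.clip(b.y_min * sy + y0, y0, y1)
            ny1 = np.clip(b.y_max * sy + y0, y0, y1)
            if (nx1 - nx0) * (ny1 - ny0) < 1.0:
                continue
            out_boxes.append(BoundingBox(b.class_id, nx0, ny0, nx1, ny1,
                                         b.confidence))
    return canvas, out_boxes


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------

def kmeans_anchors(boxes: list[BoundingBox], n_levels: int, seed: int = 0,
                   iters: int = 30) -> np.ndarray:
    """K-means over box (w, h) with an IoU-style distance; 3 anchors per
    level, assigned to levels by ascending area."""
    k = 3 * n_levels
    wh = np.array([[b.width, b.height] for b in boxes], dtype=float)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes for {k} anchors")
    rng = np.random.default_rng(seed)
    qs = np.linspace(0.05, 0.95, k)
    centers = np.quantile(wh, qs, axis=0) * rng.uniform(0.95, 1.05, size=(k, 2))
    for _ in range(iters):
        ratio = wh[:, None, :] / centers[None, :, :]
        d = 1 - np.minimum(ratio, 1 / ratio).prod(axis=2)  # 1 - IoU of aligned boxes
        assign = d.argmin(axis=1)
        for j in range(k):
            sel = wh[assign == j]
            if len(sel):
                centers[j] = sel.mean(axis=0)
    order = np.argsort(centers.prod(axis=1))
    return centers[order].reshape(n_levels, 3, 2)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class DetTrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 8
    epochs: int = 60
    seed: int = 0
    mosaic_prob: float = 1.0
    box_weight: float = 0.2    # heavier than the ecosystem's 0.05: tiny
                               # boxes need sharp sub-cell localization
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    eval_every: int = 1
    lr_final_factor: float = 0.1   # cosine decay floor as a fraction of lr
    close_mosaic: float = 0.25     # disable Mosaic for this final fraction
                                   # of epochs so late training sees
                                   # undistorted object scales


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    m = (a.data < b.data).astype(a.data.dtype)
    return a * Tensor(m) + b * Tensor(1.0 - m)


def _tmax(a: Tensor, b: Tensor) -> Tensor:
    m = (a.data > b.data).astype(a.data.dtype)
    return a * Tensor(m) + b * Tensor(1.0 - m)


def _ciou(px, py, pw, ph, gx, gy, gw, gh) -> Tensor:
    """Complete IoU between predicted and target boxes (grid units).

    Penalises centre distance relative to the enclosing box diagonal and
    aspect-ratio mismatch, which speeds convergence on tiny boxes where
    plain IoU gradients vanish.
    """
    eps = 1e-7
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = gx - gw * 0.5, gx + gw * 0.5
    gy1, gy2 = gy - gh * 0.5, gy + gh * 0.5
    iw = (_tmin(px2, gx2) - _tmax(px1, gx1)).clip(0, 1e9)
    ih = (_tmin(py2, gy2) - _tmax(py1, gy1)).clip(0, 1e9)
    inter = iw * ih
    union = pw * ph + gw * gh - inter + eps
    iou = inter / union
    cw = _tmax(px2, gx2) - _tmin(px1, gx1)
    ch = _tmax(py2, gy2) - _tmin(py1, gy1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    v = (4.0 / np.pi**2) * ((gw / (gh + eps)).arctan() - (pw / (ph + eps)).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))
    return iou - rho2 / c2 - v * alpha


def _best_anchor(w: float, h: float, anchors: np.ndarray) -> tuple[int, int]:
    """(level, anchor) whose (w, h) best fits the box under the aligned
    intersection-over-union used for the k-means distance."""
    wh = np.array([w, h])
    ratio = wh[None, None, :] / anchors
    fit = np.minimum(ratio, 1 / ratio).prod(axis=2)
    lvl, ai = np.unravel_index(fit.argmax(), fit.shape)
    return int(lvl), int(ai)


def _build_targets(boxes_per_image, cfg: DetectorConfig, anchors: np.ndarray):
    """Anchor assignment with the two-neighbour-cell rule.

    Returns, per level, index arrays (img, anchor, gj, gi) and target
    (x, y, w, h, cls) in grid units.
    """
    best: dict[tuple[int, int], tuple[int, int]] = {}
    if cfg.anchor_match == "best":
        for bi, boxes in enumerate(boxes_per_image):
            for k, b in enumerate(boxes):
                best[(bi, k)] = _best_anchor(b.width, b.height, anchors)
    out = []
    for lvl, stride in enumerate(cfg.active_strides):
        g = cfg.input_size // stride
        idx_b, idx_a, idx_j, idx_i, tgt = [], [], [], [], []
        anc = anchors[lvl] / stride   # grid units
        for bi, boxes in enumerate(boxes_per_image):
            for k, b in enumerate(boxes):
                gw, gh = b.width / stride, b.height / stride
                gx = (b.x_min + b.x_max) / 2 / stride
                gy = (b.y_min + b.y_max) / 2 / stride
                if (cfg.anchor_match == "ratio"
                        and max(gw, gh) < cfg.min_size_per_stride):
                    continue   # cell too coarse to localize this box
                for ai in range(3):
                    if cfg.anchor_match == "best":
                        if best[(bi, k)] != (lvl, ai):
                            continue
                    else:
                        r = np.array([gw, gh]) / anc[ai]
                        if np.maximum(r, 1 / r).max() >= cfg.anchor_t:
                            continue
                    ci, cj = int(gx), int(gy)
                    cells = {(ci, cj)}
                    fx, fy = gx - ci, gy - cj
                    if fx < 0.5 and ci > 0:
                        cells.add((ci - 1, cj))
                    elif fx >= 0.5 and ci < g - 1:
                        cells.add((ci + 1, cj))
                    if fy < 0.5 and cj > 0:
                        cells.add((ci, cj - 1))
                    elif fy >= 0.5 and cj < g - 1:
                        cells.add((ci, cj + 1))
                    for cc, jj in cells:
                        if not (0 <= cc < g and 0 <= jj < g):
                            continue
                        idx_b.append(bi)
                        idx_a.append(ai)
                        idx_j.append(jj)
                        idx_i.append(cc)
                        tgt.append((gx, gy, gw, gh, b.class_id))
        out.append((np.array(idx_b, dtype=np.intp), np.array(idx_a, dtype=np.intp),
                    np.array(idx_j, dtype=np.intp), np.array(idx_i, dtype=np.intp),
                    np.array(tgt, dtype=np.float32).reshape(-1, 5)))
    return out


_LEVEL_BALANCE = {4: (4.0, 1.0, 0.25, 0.06), 3: (4.0, 1.0, 0.4)}


def detection_loss(raw: list[Tensor], boxes_per_image, cfg: DetectorConfig,
                   anchors: np.ndarray, tcfg: DetTrainConfig):
    """Composite CIoU + objectness-BCE + class-BCE loss."""
    targets = _build_targets(boxes_per_image, cfg, anchors)
    balance = _LEVEL_BALANCE[cfg.n_levels]
    nb = len(boxes_per_image)
    lbox = Tensor(np.float32(0.0))
    lobj = Tensor(np.float32(0.0))
    lcls = Tensor(np.float32(0.0))
    for lvl, (grid, stride, (ib, ia, ij, ii, tgt)) in enumerate(
            zip(raw, cfg.active_strides, targets)):
        n, _, h, w = grid.shape
        p = grid.reshape(n, 3, 5 + cfg.n_classes, h, w).transpose(0, 1, 3, 4, 2)
        tobj = np.zeros((n, 3, h, w), dtype=np.float32)
        if len(ib):
            sel = p[(ib, ia, ij, ii)]            # (M, 5+nc)
            sxy = sel[:, 0:2].sigmoid() * 2.0 - 0.5
            swh = (sel[:, 2:4].sigmoid() * 2.0) ** 2
            anc = (anchors[lvl] / stride)[ia]     # (M, 2)
            px = sxy[:, 0] + Tensor(ii.astype(np.float32))
            py = sxy[:, 1] + Tensor(ij.astype(np.float32))
            pw = swh[:, 0] * Tensor(anc[:, 0].astype(np.float32))
            ph = swh[:, 1] * Tensor(anc[:, 1].astype(np.float32))
            ciou = _ciou(px, py, pw, ph,
                         Tensor(tgt[:, 0]), Tensor(tgt[:, 1]),
                         Tensor(tgt[:, 2]), Tensor(tgt[:, 3]))
            lbox = lbox + (1.0 - ciou).mean()
            tobj[(ib, ia, ij, ii)] = np.clip(ciou.data, 0, None)
            if cfg.n_classes > 1:
                onehot = np.eye(cfg.n_classes, dtype=np.float32)[tgt[:, 4].astype(int)]
                lcls = lcls + F.bce_with_logits(sel[:, 5:], onehot)
        pobj = p[..., 4]
        lobj = lobj + F.bce_with_logits(pobj, tobj) * balance[lvl]
    total = (lbox * tcfg.box_weight + lobj * tcfg.obj_weight
             + lcls * tcfg.cls_weight) * float(nb)
    return total, {"box": float(lbox.data), "obj": float(lobj.data),
                   "cls": float(lcls.data)}


def _resize_sample(img: np.ndarray, boxes, size: int):
    """Plain (non-letterbox) resize with box rescaling."""
    h, w = img.shape[:2]
    for b in boxes:
        if not (0 <= b.x_min and b.x_max <= w and 0 <= b.y_min and b.y_max <= h):
            raise ValueError("box outside image")
    if (h, w) == (size, size):
        return img, list(boxes)
    out = np.asarray(PILImage.fromarray(img).resize((size, size), PILImage.BILINEAR))
    sx, sy = size / w, size / h
    return out, [BoundingBox(b.class_id, b.x_min * sx, b.y_min * sy,
                             b.x_max * sx, b.y_max * sy, b.confidence)
                 for b in boxes]


def train_detector(model: P2Detector, dataset, tcfg: DetTrainConfig,
                   val_data=None):
    """Train on ``(image, boxes)`` pairs; returns per-epoch history.

    Images are plainly resized to the network input size; Mosaic is
    applied with probability ``tcfg.mosaic_prob`` per training sample.
    Anchors default to k-means over the training boxes when the config
    does not fix them.
    """
    cfg = model.cfg
    size = cfg.input_size
    data = [_resize_sample(img, boxes, size) for img, boxes in dataset]
    if cfg.anchors is not None:
        anchors = cfg.level_anchors()
    else:
        all_boxes = [b for _, boxes in data for b in boxes]
        anchors = kmeans_anchors(all_boxes, cfg.n_levels, seed=tcfg.seed)
        logger.info("k-means anchors per level: %s", anchors.round(1).tolist())
    model.anchors = anchors
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.parameters(), lr=tcfg.learning_rate)
    history = []
    for epoch in range(tcfg.epochs):
        model.train()
        f = tcfg.lr_final_factor
        opt.lr = tcfg.learning_rate * (
            f + (1 - f) * 0.5 * (1 + np.cos(np.pi * epoch / max(tcfg.epochs - 1, 1))))
        order = rng.permutation(len(data))
        losses, parts = [], {"box": [], "obj": [], "cls": []}
        mosaic_on = epoch < (1 - tcfg.close_mosaic) * tcfg.epochs
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            imgs, boxes_pi = [], []
            for i in idx:
                if mosaic_on and rng.random() < tcfg.mosaic_prob:
                    others = rng.integers(0, len(data), size=3)
                    four = [data[i]] + [data[j] for j in others]
                    img, boxes = mosaic_augment(four, size, int(rng.integers(2**31)))
                else:
                    img, boxes = data[i]
                imgs.append(img)
                boxes_pi.append(boxes)
            x = Tensor(np.ascontiguousarray(
                np.stack(imgs).transpose(0, 3, 1, 2)).astype(np.float32) / 255.0)
            raw = model(x)
            loss, comp = detection_loss(raw, boxes_pi, cfg, anchors, tcfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            for k, v in comp.items():
                parts[k].append(v)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 **{f"loss_{k}": float(np.mean(v)) for k, v in parts.items()}}
        if val_data is not None and (epoch + 1) % tcfg.eval_every == 0:
            entry["val_map50"] = evaluate_detector(model, val_data)
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return model, history


def detect(model: P2Detector, img: np.ndarray,
           conf_threshold: float | None = None) -> list[BoundingBox]:
    """Run the detector on one RGB image; boxes come back in the
    original image's pixel coordinates after NMS."""
    cfg = model.cfg
    h, w = img.shape[:2]
    resized, _ = _resize_sample(img, [], cfg.input_size)
    model.eval()
    x = Tensor(np.ascontiguousarray(
        resized.transpose(2, 0, 1))[None].astype(np.float32) / 255.0)
    raw = [t.data for t in model(x)]
    boxes = decode_predictions(raw, cfg, conf_threshold,
                               anchors=getattr(model, "anchors", None))[0]
    boxes = nms(boxes, cfg.nms_iou)
    sx, sy = w / cfg.input_size, h / cfg.input_size
    return [BoundingBox(b.class_id, b.x_min * sx, b.y_min * sy,
                        b.x_max * sx, b.y_max * sy, b.confidence)
            for b in boxes]


def evaluate_detector(model: P2Detector, dataset,
                      iou_threshold: float = 0.5) -> float:
    """mAP@IoU over a dataset of ``(image, gt_boxes)`` pairs."""
    from .metrics import detection_map

    preds, gts = [], []
    for img, boxes in dataset:
        preds.append(detect(model, img, conf_threshold=0.001))
        gts.append(list(boxes))
    m, _ = detection_map(preds, gts, iou_threshold)
    return m


def save_detector(model: P2Detector, path: str | Path) -> None:
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    cfg = asdict(model.cfg)
    np.savez(path, __config__=json.dumps(cfg),
             __anchors__=getattr(model, "anchors", model.cfg.level_anchors()),
             **state)


def load_detector(path: str | Path) -> P2Detector:
    with np.load(path, allow_pickle=False) as z:
        cfg_d = json.loads(str(z["__config__"]))
        for key in ("strides",):
            cfg_d[key] = tuple(cfg_d[key])
        if cfg_d.get("anchors") is not None:
            cfg_d["anchors"] = tuple(map(tuple, cfg_d["anchors"]))
        model = P2Detector(DetectorConfig(**cfg_d))
        model.anchors = z["__anchors__"]
        model.load_state_dict({k[6:]: z[k] for k in z.files if k.startswith("param/")})
    return model
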