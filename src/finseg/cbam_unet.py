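"""U-shaped encoder–decoder segmentation network with optional CBAM.

The same architecture serves three jobs at different head widths:
background removal (2 classes), part segmentation (4 classes:
background/belly/loin/back) and defect-crop segmentation (3 classes:
background/fat/bruise).  The convolutional block attention module
(CBAM) multiplies each encoder stage's output by a channel gate (pooled
descriptors through a shared bottleneck perceptron) and then a spatial
gate (channel-pooled maps through a wide convolution), both squashed to
(0, 1) by the logistic function.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concatenate
from .preprocess import AugmentPolicy, augment

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "UNetConfig",
    "UNet",
    "build_unet",
    "SegTrainConfig",
    "train_segmenter",
    "predict_mask",
    "evaluate_segmenter",
    "save_checkpoint",
    "load_checkpoint",
]


class ChannelAttention(nn.Module):
    """Per-channel gate from global average- and max-pooled descriptors.

    Both descriptors pass through one shared two-layer perceptron
    (C -> C/r -> C with a rectifier between); the two outputs are summed
    and squashed, giving weights in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))                # (N, C)
        mx = x.max(axis=(2, 3))
        out = (self.fc2(self.fc1(avg).relu())
               + self.fc2(self.fc1(mx).relu())).sigmoid()
        n, c = out.shape
        return out.reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    """Per-location gate from channel-wise mean and max maps through a
    single wide convolution (odd kernel, same padding)."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concatenate([avg, mx], axis=1)).sigmoid()


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention; preserves shape."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction)
        self.spatial = SpatialAttention(spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel(x)
        return x * self.spatial(x)


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 3
    n_classes: int = 4
    base_width: int = 64
    depth: int = 4
    use_cbam: bool = False
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    cbam_in_decoder: bool = False
    batch_norm: bool = True

    def __post_init__(self):
        if self.depth < 1 or self.base_width < 1 or self.n_classes < 2:
            raise ValueError("invalid UNet configuration")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * 2 ** self.depth


def _conv_block(cin: int, cout: int, bn: bool) -> nn.Sequential:
    mods: list[nn.Module] = [nn.Conv2d(cin, cout, 3, padding=1, bias=not bn)]
    if bn:
        mods.append(nn.BatchNorm2d(cout))
    mods.append(nn.ReLU())
    mods.append(nn.Conv2d(cout, cout, 3, padding=1, bias=not bn))
    if bn:
        mods.append(nn.BatchNorm2d(cout))
    mods.append(nn.ReLU())
    return nn.Sequential(*mods)


class UNet(nn.Module):
    """Encoder halves resolution and doubles width per stage; the decoder
    mirrors it, concatenating the same-resolution encoder feature before
    each convolution pair; a 1x1 head maps to class logits."""

    def __init__(self, cfg: UNetConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.base_width
        self.enc = [
            _conv_block(cfg.in_channels if i == 0 else w * 2 ** (i - 1),
                        w * 2 ** i, cfg.batch_norm)
            for i in range(cfg.depth)
        ]
        self.enc_cbam = [
            CBAM(w * 2 ** i, cfg.cbam_reduction, cfg.spatial_kernel)
            if cfg.use_cbam else nn.Identity()
            for i in range(cfg.depth)
        ]
        self.pool = nn.MaxPool2d(2)
        self.bottleneck = _conv_block(w * 2 ** (cfg.depth - 1),
                                      w * 2 ** cfg.depth, cfg.batch_norm)
        self.bottleneck_cbam = (
            CBAM(w * 2 ** cfg.depth, cfg.cbam_reduction, cfg.spatial_kernel)
            if cfg.use_cbam else nn.Identity()
        )
        self.up = [
            nn.ConvTranspose2d(w * 2 ** (i + 1), w * 2 ** i)
            for i in reversed(range(cfg.depth))
        ]
        self.dec = [
            _conv_block(w * 2 ** (i + 1), w * 2 ** i, cfg.batch_norm)
            for i in reversed(range(cfg.depth))
        ]
        self.dec_cbam = [
            CBAM(w * 2 ** i, cfg.cbam_reduction, cfg.spatial_kernel)
            if (cfg.use_cbam and cfg.cbam_in_decoder) else nn.Identity()
            for i in reversed(range(cfg.depth))
        ]
        self.head = nn.Conv2d(w, cfg.n_classes, 1)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.cfg.depth
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by 2^depth={div}")
        skips = []
        for blk, att in zip(self.enc, self.enc_cbam):
            x = att(blk(x))
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck_cbam(self.bottleneck(x))
        for up, blk, att, skip in zip(self.up, self.dec, self.dec_cbam,
                                      reversed(skips)):
            x = up(x)
            assert x.shape == skip.shape, "skip/decoder resolution mismatch"
            x = att(blk(concatenate([skip, x], axis=1)))
        return self.head(x)


def build_unet(cfg: UNetConfig, seed: int | None = None) -> UNet:
    if seed is not None:
        nn.seed_init(seed)
    return UNet(cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    loss_name: str = "ce_dice"
    seed: int = 0
    augment_policy: AugmentPolicy | None = field(default_factory=AugmentPolicy)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def _to_input(images: np.ndarray) -> Tensor:
    """uint8 (N,H,W,3) -> float32 (N,3,H,W) in [0,1]."""
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2)).astype(np.float32) / 255.0
    return Tensor(x)


def _soft_dice_loss(logits: Tensor, labels: np.ndarray, n_classes: int) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    p = e / e.sum(axis=1, keepdims=True)
    onehot = np.eye(n_classes, dtype=np.float32)[labels].transpose(0, 3, 1, 2)
    inter = (p * onehot).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + 1.0) / (denom + 1.0)
    return 1.0 - dice.mean()


def _seg_loss(logits: Tensor, labels: np.ndarray, n_classes: int, name: str) -> Tensor:
    ce = F.softmax_cross_entropy(logits, labels)
    if name == "ce":
        return ce
    if name == "ce_dice":
        return ce + _soft_dice_loss(logits, labels, n_classes)
    raise ValueError(f"unknown loss {name!r}")


def train_segmenter(model: UNet, dataset, cfg: SegTrainConfig, val_data=None):
    """Train on ``(image, mask)`` pairs; returns per-epoch history.

    Online augmentation (when ``cfg.augment_policy`` is set) re-draws the
    photometric and geometric jitter for every sample every epoch, with
    seeds derived from ``cfg.seed`` so runs are reproducible.
    """
    n_classes = model.cfg.n_classes
    for img, mask in dataset:
        if img.shape[:2] != mask.shape:
            raise ValueError("image/mask size mismatch in dataset")
        if mask.max() >= n_classes:
            raise ValueError(f"mask label {mask.max()} >= n_classes {n_classes}")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, masks = [], []
            for j, i in enumerate(idx):
                img, mask = dataset[i]
                if cfg.augment_policy is not None:
                    aug_seed = int(rng.integers(2**31))
                    img, mask, _ = augment(img, mask, None, cfg.augment_policy,
                                           aug_seed)
                imgs.append(img)
                masks.append(mask)
            x = _to_input(np.stack(imgs))
            y = np.stack(masks).astype(np.int64)
            logits = model(x)
            loss = _seg_loss(logits, y, n_classes, cfg.loss_name)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            entry.update(evaluate_segmenter(model, val_data, cfg.loss_name))
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return model, history


def evaluate_segmenter(model: UNet, data, loss_name: str = "ce_dice") -> dict:
    """Mean loss, per-image-averaged mIoU and pixel accuracy on a dataset."""
    from .metrics import mean_iou, pixel_accuracy

    model.eval()
    n_classes = model.cfg.n_classes
    losses, mious, pas = [], [], []
    for img, mask in data:
        x = _to_input(img[None])
        logits = model(x)
        losses.append(float(_seg_loss(logits, mask[None].astype(np.int64),
                                      n_classes, loss_name).data))
        pred = logits.data[0].argmax(axis=0).astype(np.uint8)
        _, miou = mean_iou(pred, mask, n_classes - 1)
        mious.append(miou)
        pas.append(pixel_accuracy(pred, mask))
    return {
        "val_loss": float(np.mean(losses)),
        "val_miou": float(np.mean(mious)),
        "val_pa": float(np.mean(pas)),
    }


def predict_mask(model: UNet, img: np.ndarray):
    """Argmax mask plus per-class probability maps for one RGB image."""
    div = 2 ** model.cfg.depth
    if img.shape[0] % div or img.shape[1] % div:
        raise ValueError(f"image dims {img.shape[:2]} not divisible by {div}")
    model.eval()
    logits = model(_to_input(img[None])).data[0]
    probs = F.softmax(logits, axis=0)
    return probs.argmax(axis=0).astype(np.uint8), probs


# ---------------------------------------------------------------------------
# Checkpoints: single .npz archive with the config embedded
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path: str | Path) -> None:
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __config__=json.dumps(asdict(model.cfg)), **state)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(path, allow_pickle=False) as z:
        cfg = UNetConfig(**json.loads(str(z["__config__"])))
        model = UNet(cfg)
        model.load_state_dict({k[6:]: z[k] for k in z.files if k.startswith("param/")})
    return model
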