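"""One-file YAML configuration for the full pipeline.

A config file may carry any of the sections ``synthetic:``, ``augment:``,
``segmenter:``, ``seg_train:``, ``detector:``, ``det_train:`` and
``two_stage:``; each maps 1:1 onto the corresponding dataclass, with
unknown keys rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .cbam_unet import SegTrainConfig, UNetConfig
from .p2_yolo import DetectorConfig, DetTrainConfig
from .preprocess import AugmentPolicy
from .synthetic import SyntheticSpec
from .two_stage import TwoStageConfig

__all__ = ["load_config", "SECTIONS"]

SECTIONS = {
    "synthetic": SyntheticSpec,
    "augment": AugmentPolicy,
    "segmenter": UNetConfig,
    "seg_train": SegTrainConfig,
    "detector": DetectorConfig,
    "det_train": DetTrainConfig,
    "two_stage": TwoStageConfig,
}

_TUPLE_FIELDS = {
    "band_fractions", "defect_count_range", "defect_radius_range",
    "fat_color", "bruise_color", "background_color", "scale_range",
    "strides", "anchors",
}


def _build(cls, doc: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in doc.items():
        if key in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Parse a pipeline YAML into a dict of config dataclasses.

    Only sections present in the file appear in the result.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(doc) - set(SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    out = {}
    for name, sub in doc.items():
        out[name] = _build(SECTIONS[name], sub or {})
    return out
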