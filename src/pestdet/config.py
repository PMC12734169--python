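"""Variant/run configuration files (YAML).

A config file bundles the ablation switches with the run settings, e.g.::

    variant:
      ema: true
      fusion: true
      wiou: true
      c3k2b: true
    nc: 5
    imgsz: 640
    box_loss: wiou_v3      # ciou | wiou_v1 | wiou_v3
    alpha: 1.9
    delta: 3.0
    momentum: 0.99
    nms:
      conf: 0.25
      iou: 0.45
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .netgraph import VariantFlags
from .train import TrainConfig

BOX_LOSSES = ("ciou", "wiou_v1", "wiou_v3")


def load_variant_config(path) -> tuple[VariantFlags, TrainConfig, dict]:
    """Read a config file -> (flags, train config, nms settings)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    v = raw.get("variant", {})
    flags = VariantFlags(
        ema=bool(v.get("ema", False)), fusion=bool(v.get("fusion", False)),
        wiou=bool(v.get("wiou", False)), c3k2b=bool(v.get("c3k2b", False)),
    )
    box_loss = raw.get("box_loss", "wiou_v3" if flags.wiou else "ciou")
    if box_loss not in BOX_LOSSES:
        raise ValueError(f"box_loss must be one of {BOX_LOSSES}, got {box_loss!r}")
    cfg = TrainConfig(
        epochs=int(raw.get("epochs", 100)),
        imgsz=int(raw.get("imgsz", 640)),
        batch=int(raw.get("batch", 8)),
        lr=float(raw.get("lr", 0.01)),
        momentum=float(raw.get("momentum_sgd", 0.937)),
        weight_decay=float(raw.get("weight_decay", 0.0005)),
        box_loss=box_loss,
        wiou_alpha=float(raw.get("alpha", 1.9)),
        wiou_delta=float(raw.get("delta", 3.0)),
        wiou_momentum=float(raw.get("momentum", 0.99)),
        seed=int(raw.get("seed", 0)),
    )
    nms = dict(conf=0.25, iou=0.45)
    nms.update(raw.get("nms", {}))
    return flags, cfg, nms


def save_variant_config(path, flags: VariantFlags, cfg: TrainConfig,
                        nms: dict | None = None):
    doc = {
        "variant": {k: getattr(flags, k) for k in ("ema", "fusion", "wiou", "c3k2b")},
        "nc": 5,
        **{k: v for k, v in asdict(cfg).items()
           if k in ("epochs", "imgsz", "batch", "lr", "weight_decay", "box_loss", "seed")},
        "alpha": cfg.wiou_alpha, "delta": cfg.wiou_delta, "momentum": cfg.wiou_momentum,
        "nms": nms or {"conf": 0.25, "iou": 0.45},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
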