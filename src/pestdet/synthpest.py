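"""Synthetic labelled pest scenes with the statistical structure of dense
small-target melon-pest imagery.

Five class archetypes mirror the real label set:

====  =================  ==========================================
id    class              archetype
====  =================  ==========================================
0     aphids             small dark ellipses, spatially clustered
1     leafminers         serpentine bright trail; the box is the
                         trail extent, so most of the box interior
                         is background (deliberately low-quality
                         geometry that exercises the focusing loss)
2     moths              medium textured blob
3     red-melon beetles  medium reddish blob
4     whiteflies         tiny bright ellipses, clustered, each
                         occupying roughly 1-3 percent of the image
====  =================  ==========================================

Scenes carry a Poisson-distributed number of targets (mean 3.5 per image by
default), a smooth leaf-green background texture, and YOLO-format labels
(``class cx cy w h``, normalised).  Everything is driven by a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("aphids", "leafminers", "moths", "red-melon-beetles", "whiteflies")
NC = len(CLASS_NAMES)


class PlacementError(RuntimeError):
    pass


@dataclass
class SceneSpec:
    size: int = 320
    mean_targets: float = 3.5
    class_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    cluster_prob: float = 0.5        # chance that a tiny-target class spawns a cluster
    texture_scale: float = 12.0      # background smoothing radius, pixels
    max_retries: int = 80
    seed: int = 0

    def __post_init__(self):
        if self.mean_targets <= 0:
            raise ValueError("mean target density must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-6 or len(self.class_mix) != NC:
            raise ValueError("class_mix must be a length-5 probability vector")


@dataclass
class LabeledScene:
    image: np.ndarray                       # (h, w, 3) uint8
    labels: list[tuple[int, float, float, float, float]]  # cls, cx, cy, w, h in [0,1]

    def label_lines(self) -> list[str]:
        return [
            f"{c} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
            for c, cx, cy, w, h in self.labels
        ]


def _background(rng: np.random.Generator, s: int, scale: float) -> np.ndarray:
    base = np.array([58.0, 112.0, 48.0])      # leaf green
    tex = gaussian_filter(rng.normal(0, 1, (s, s)), scale)
    tex = tex / (np.abs(tex).max() + 1e-9)
    img = np.empty((s, s, 3))
    for ch in range(3):
        fine = gaussian_filter(rng.normal(0, 1, (s, s)), 2.0) * 6.0
        img[..., ch] = base[ch] * (1.0 + 0.35 * tex) + fine
    return img


def _ellipse_mask(s, cx, cy, rx, ry, angle, rng=None):
    ys, xs = np.mgrid[0:s, 0:s]
    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = xs - cx, ys - cy
    u = (dx * ca + dy * sa) / max(rx, 1e-6)
    v = (-dx * sa + dy * ca) / max(ry, 1e-6)
    return u * u + v * v <= 1.0


def _paint(img, mask, color, rng, noise=8.0):
    col = np.asarray(color, dtype=float) + rng.normal(0, noise, 3)
    img[mask] = 0.15 * img[mask] + 0.85 * col


def _bbox_of(mask, s, pad=1.0):
    ys, xs = np.nonzero(mask)
    x1, x2 = xs.min() - pad, xs.max() + pad
    y1, y2 = ys.min() - pad, ys.max() + pad
    cx, cy = (x1 + x2) / 2 / s, (y1 + y2) / 2 / s
    w, h = (x2 - x1) / s, (y2 - y1) / s
    return cx, cy, max(w, 1e-3), max(h, 1e-3)


def _tiny_blob(img, rng, s, bright: bool):
    """One whitefly/aphid-sized ellipse whose *label box* lands in the
    1-3 percent image-area regime."""
    frac = rng.uniform(0.014, 0.026)       # target box area fraction
    ar = rng.uniform(0.7, 1.4)
    bw = np.sqrt(frac * ar) * s
    bh = frac * s * s / bw
    rx = max(1.5, (bw - 3.0) / 2)
    ry = max(1.5, (bh - 3.0) / 2)
    cx = rng.uniform(bw / 2 + 1, s - bw / 2 - 1)
    cy = rng.uniform(bh / 2 + 1, s - bh / 2 - 1)
    mask = _ellipse_mask(s, cx, cy, rx, ry, rng.uniform(0, np.pi))
    color = (232, 236, 224) if bright else (62, 48, 38)
    _paint(img, mask, color, rng)
    if bright:  # faint wing hint kept inside the ellipse extent
        wing = _ellipse_mask(s, cx + rx * 0.35, cy, rx * 0.5, ry * 0.4, 0.4)
        img[wing] = 0.5 * img[wing] + 0.5 * np.array([210.0, 215.0, 205.0])
        mask = mask | wing
    return _bbox_of(mask, s)


def _trail(img, rng, s):
    """Serpentine bright mining trail; the label box covers its extent."""
    n_steps = int(rng.integers(40, 90))
    pos = np.array([rng.uniform(0.2 * s, 0.8 * s), rng.uniform(0.2 * s, 0.8 * s)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0, 0.5)
        pos = pos + 0.007 * s * np.array([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, 3, s - 4)
        pts.append(pos.copy())
    mask = np.zeros((s, s), dtype=bool)
    width = max(1.0, 0.005 * s) * rng.uniform(1.0, 1.8)
    ys, xs = np.mgrid[0:s, 0:s]
    for p in pts[::2]:
        mask |= (xs - p[0]) ** 2 + (ys - p[1]) ** 2 <= width ** 2
    _paint(img, mask, (214, 222, 196), rng, noise=4.0)
    return _bbox_of(mask, s)


def _blob(img, rng, s, reddish: bool):
    rx = rng.uniform(0.04, 0.09) * s
    ry = rx * rng.uniform(0.6, 1.1)
    cx = rng.uniform(rx + 2, s - rx - 2)
    cy = rng.uniform(ry + 2, s - ry - 2)
    ang = rng.uniform(0, np.pi)
    mask = _ellipse_mask(s, cx, cy, rx, ry, ang)
    color = (168, 52, 40) if reddish else (122, 104, 86)
    _paint(img, mask, color, rng)
    # simple body texture: darker head ellipse
    head = _ellipse_mask(s, cx + 0.6 * rx * np.cos(ang), cy + 0.6 * rx * np.sin(ang),
                         rx * 0.35, ry * 0.35, ang)
    img[head] = 0.4 * img[head] + 0.6 * np.array([40.0, 28.0, 24.0])
    return _bbox_of(mask | head, s)


def _boxes_overlap(b1, b2, thresh=0.5):
    x1 = max(b1[1] - b1[3] / 2, b2[1] - b2[3] / 2)
    x2 = min(b1[1] + b1[3] / 2, b2[1] + b2[3] / 2)
    y1 = max(b1[2] - b1[4] / 2, b2[2] - b2[4] / 2)
    y2 = min(b1[2] + b1[4] / 2, b2[2] + b2[4] / 2)
    inter = max(0.0, x2 - x1) * max(0.0, y2 - y1)
    smaller = min(b1[3] * b1[4], b2[3] * b2[4])
    return inter > thresh * smaller


def generate_scene(spec: SceneSpec) -> LabeledScene:
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    img = _background(rng, s, spec.texture_scale)
    n = int(rng.poisson(spec.mean_targets))
    labels: list[tuple[int, float, float, float, float]] = []
    placed = 0
    while placed < n:
        cls = int(rng.choice(NC, p=spec.class_mix))
        cluster = 1
        if cls in (0, 4) and rng.uniform() < spec.cluster_prob:
            cluster = int(rng.integers(2, 5))
        cluster = min(cluster, n - placed) or 1
        for _ in range(cluster):
            for attempt in range(spec.max_retries + 1):
                if attempt == spec.max_retries:
                    raise PlacementError("could not place target under density cap")
                snap = img.copy()
                if cls == 0:
                    box = _tiny_blob(img, rng, s, bright=False)
                elif cls == 1:
                    box = _trail(img, rng, s)
                elif cls == 2:
                    box = _blob(img, rng, s, reddish=False)
                elif cls == 3:
                    box = _blob(img, rng, s, reddish=True)
                else:
                    box = _tiny_blob(img, rng, s, bright=True)
                cand = (cls, *box)
                if any(_boxes_overlap(cand, lb) for lb in labels):
                    img = snap   # undo and retry elsewhere
                    continue
                labels.append(cand)
                break
            placed += 1
            if placed >= n:
                break
    img = np.clip(img, 0, 255).astype(np.uint8)
    labels = [
        (c, float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1)),
         float(min(w, 1.0)), float(min(h, 1.0)))
        for c, cx, cy, w, h in labels
    ]
    return LabeledScene(img, labels)


def flip_augment(scenes: list[LabeledScene], seed: int = 0) -> list[LabeledScene]:
    """One flipped copy per scene (doubling the set).

    Horizontal and vertical flips are sampled independently at probability
    one half; if both come out as identity the copy is forced to a
    horizontal flip so no exact duplicate is ever emitted.
    """
    rng = np.random.default_rng(seed)
    out = list(scenes)
    for sc in scenes:
        hf = rng.uniform() < 0.5
        vf = rng.uniform() < 0.5
        if not hf and not vf:
            hf = True
        img = sc.image
        labels = sc.labels
        if hf:
            img = img[:, ::-1]
            labels = [(c, 1.0 - cx, cy, w, h) for c, cx, cy, w, h in labels]
        if vf:
            img = img[::-1]
            labels = [(c, cx, 1.0 - cy, w, h) for c, cx, cy, w, h in labels]
        out.append(LabeledScene(np.ascontiguousarray(img), labels))
    return out


def flip_labels(labels, horizontal: bool, vertical: bool):
    out = labels
    if horizontal:
        out = [(c, 1.0 - cx, cy, w, h) for c, cx, cy, w, h in out]
    if vertical:
        out = [(c, cx, 1.0 - cy, w, h) for c, cx, cy, w, h in out]
    return out


def split_dataset(ids_by_class: dict[int, list], ratios=(0.8, 0.1, 0.1),
                  seed: int = 0) -> dict[str, list]:
    """Stratified split before augmentation: per class, train gets
    floor(r_train * n), val floor(r_val * n), test the remainder."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    splits = {"train": [], "val": [], "test": []}
    for cls in sorted(ids_by_class):
        ids = list(ids_by_class[cls])
        rng.shuffle(ids)
        n = len(ids)
        n_train = int(np.floor(ratios[0] * n))
        n_val = int(np.floor(ratios[1] * n))
        splits["train"].extend(ids[:n_train])
        splits["val"].extend(ids[n_train:n_train + n_val])
        splits["test"].extend(ids[n_train + n_val:])
    return splits


# ------------------------------------------------------------------ file IO
def write_label_file(path, labels):
    Path(path).write_text("".join(
        f"{c} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n" for c, cx, cy, w, h in labels
    ))


def read_label_file(path):
    labels = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        labels.append((int(parts[0]), *(float(v) for v in parts[1:5])))
    return labels


def write_dataset(root, scenes: dict, splits: dict[str, list],
                  augment_train: bool = True, seed: int = 0) -> Path:
    """Write the standard YOLO layout plus a manifest.

    ``scenes``: id -> LabeledScene.  Flip augmentation doubles the training
    split only; validation and test are written untouched.
    """
    import yaml
    from PIL import Image

    root = Path(root)
    out_splits = {}
    for split, ids in splits.items():
        items = [(i, scenes[i]) for i in ids]
        if augment_train and split == "train":
            aug = flip_augment([sc for _, sc in items], seed=seed)
            items = items + [
                (f"{i}_aug", sc) for (i, _), sc in zip(items, aug[len(items):])
            ]
        out_splits[split] = items
        (root / "images" / split).mkdir(parents=True, exist_ok=True)
        (root / "labels" / split).mkdir(parents=True, exist_ok=True)
        for name, sc in items:
            Image.fromarray(sc.image).save(root / "images" / split / f"{name}.png")
            write_label_file(root / "labels" / split / f"{name}.txt", sc.labels)
    manifest = {
        "path": str(root),
        "names": {i: n for i, n in enumerate(CLASS_NAMES)},
        "nc": NC,
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
    }
    (root / "dataset.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return root / "dataset.yaml"


def load_split(root, split: str):
    """Load (images float32 CHW in [0,1], labels) lists for a split."""
    from PIL import Image

    root = Path(root)
    imgs, labels = [], []
    for img_path in sorted((root / "images" / split).glob("*.png")):
        arr = np.asarray(Image.open(img_path), dtype=np.float32) / 255.0
        imgs.append(arr.transpose(2, 0, 1))
        labels.append(read_label_file(root / "labels" / split / f"{img_path.stem}.txt"))
    return imgs, labels
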