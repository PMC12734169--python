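"""Detector assembly: explicit layer graphs for the baseline and every
ablation variant, parameter/FLOP profiling, forward inference and greedy NMS.

A :class:`GraphSpec` is an ordered list of layers with from-indices (a DAG:
every reference points to an earlier layer).  The four ablation switches in
:class:`VariantFlags` correspond to the improvements studied at nano scale:

* ``ema``    — two EMA attention blocks inserted at the backbone tail
  (after the stride-32 Conv and after the final attention stage);
* ``fusion`` — the neck/head rewiring that advances the mid-scale fusion to
  the stride-8 level so spatially detailed features reach the heads earlier;
* ``c3k2b``  — the C3k2 -> C3k2-B substitution at the three marked sites;
* ``wiou``   — box-loss swap only; the graph (and hence the profile) is
  untouched.

FLOPs are reported at 640x640 under a fixed convention: one multiply-add
counts as two FLOPs; batch norm is folded into the preceding convolution
(zero extra cost); sigmoid-family activations cost nine FLOPs per element
(exponential evaluated polynomially at six, plus add, divide, and the
product with the gated value); attention matrix products and softmaxes
follow the family's module-level accounting and are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .arblocks import C3k2B, C3k2BSpec
from .attention import EMA
from .blocks import REG_MAX, A2C2f, C3k2, Detect, dfl_expectation
from .nn.autograd import Tensor, concat, no_grad, sigmoid
from .nn.layers import Conv, DWConv, Module, Profile, Sequential, Upsample


@dataclass(frozen=True)
class VariantFlags:
    ema: bool = False
    fusion: bool = False
    wiou: bool = False
    c3k2b: bool = False

    @classmethod
    def full(cls):
        return cls(True, True, True, True)

    def tag(self) -> str:
        on = [n for n in ("ema", "fusion", "wiou", "c3k2b") if getattr(self, n)]
        return "+".join(on) if on else "baseline"


@dataclass
class LayerSpec:
    index: int
    frm: tuple[int, ...]          # from-indices (negative = relative)
    kind: str                     # conv | dwconv | c3k2 | c3k2b | a2c2f | ema | upsample | concat | detect
    args: dict = field(default_factory=dict)


@dataclass
class GraphSpec:
    layers: list[LayerSpec]
    nc: int
    flags: VariantFlags
    strides: tuple[int, ...] = (8, 16, 32)

    def validate(self):
        for ls in self.layers:
            for f in ls.frm:
                if f >= ls.index:
                    raise ValueError(f"layer {ls.index} references later layer {f}")
        n_detect = sum(1 for ls in self.layers if ls.kind == "detect")
        if n_detect != 1:
            raise ValueError(f"exactly one detect layer required, found {n_detect}")


@dataclass
class ProfileReport:
    params: int
    flops: float                   # raw FLOPs at 640x640
    imgsz: int = 640

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.flops / 1e9, 1)

    def __str__(self):
        return f"{self.params_m:.2f} M params / {self.gflops:.1f} GFLOPs @ {self.imgsz}"


def build_variant(flags: VariantFlags, nc: int = 5) -> GraphSpec:
    """Assemble the nano-scale layer graph for an ablation variant."""
    if nc < 1:
        raise ValueError("nc must be >= 1")
    L: list[LayerSpec] = []

    def add(frm, kind, **args) -> int:
        idx = len(L)
        frm = (frm,) if isinstance(frm, int) else tuple(frm)
        L.append(LayerSpec(idx, frm, kind, args))
        return idx

    site = "c3k2b" if flags.c3k2b else "c3k2"
    x = add((), "conv", c1=3, c2=16, k=3, s=2)
    x = add(x, "conv", c1=16, c2=32, k=3, s=2, g=2)
    x = add(x, site, c1=32, c2=64, e=0.25)
    x = add(x, "conv", c1=64, c2=64, k=3, s=2, g=4)
    p3 = add(x, site, c1=64, c2=128, e=0.25)
    x = add(p3, "conv", c1=128, c2=128, k=3, s=2)
    p4 = add(x, "a2c2f", c1=128, c2=128, n=2, a2=True, area=4)
    x = add(p4, "conv", c1=128, c2=256, k=3, s=2)
    if flags.ema:
        x = add(x, "ema", c=256, g=8)
    x = add(x, "a2c2f", c1=256, c2=256, n=2, a2=True, area=1)
    if flags.ema:
        x = add(x, "ema", c=256, g=8)
    tail = x

    u = add(tail, "upsample", scale=2)
    c = add((u, p4), "concat")
    t1 = add(c, "a2c2f", c1=384, c2=128, n=1, a2=False)
    u = add(t1, "upsample", scale=2)
    c = add((u, p3), "concat")
    t2 = add(c, "a2c2f", c1=256, c2=64, n=1, a2=False)          # P3 head input

    if not flags.fusion:
        d = add(t2, "conv", c1=64, c2=64, k=3, s=2)
        c = add((d, t1), "concat")
        m1 = add(c, "a2c2f", c1=192, c2=128, n=1, a2=False)     # P4 head input
        d2 = add(m1, "conv", c1=128, c2=128, k=3, s=2)
        c = add((d2, tail), "concat")
        p5h = add(c, site, c1=384, c2=256, e=0.5, c3k=True)     # P5 head input
        add((t2, m1, p5h), "detect", nc=nc)
    else:
        u4 = add(tail, "upsample", scale=4)
        c = add((t2, u4), "concat")
        m0 = add(c, "a2c2f", c1=320, c2=128, n=1, a2=False)     # fused at stride 8
        dws = add(m0, "dwconv", c=128, k=3, s=2)
        m1 = add(dws, "conv", c1=128, c2=128, k=1, s=1)         # P4 head input
        d2 = add(m1, "conv", c1=128, c2=128, k=3, s=2)
        c = add((d2, tail), "concat")
        p5h = add(c, site, c1=384, c2=256, e=0.5, c3k=True)     # P5 head input
        add((t2, m1, p5h), "detect", nc=nc)

    spec = GraphSpec(L, nc, flags)
    spec.validate()
    return spec


class DetectorModel(Module):
    """Executable network instantiated from a GraphSpec."""

    def __init__(self, spec: GraphSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        mods = []
        for ls in spec.layers:
            a = ls.args
            if ls.kind == "conv":
                mods.append(Conv(a["c1"], a["c2"], a["k"], a["s"],
                                 g=a.get("g", 1), rng=rng))
            elif ls.kind == "dwconv":
                mods.append(DWConv(a["c"], a["k"], a["s"], rng=rng))
            elif ls.kind == "c3k2":
                mods.append(C3k2(a["c1"], a["c2"], n=1, c3k=a.get("c3k", False),
                                 e=a["e"], rng=rng))
            elif ls.kind == "c3k2b":
                mods.append(C3k2B(C3k2BSpec(a["c1"], a["c2"], n=1, e=a["e"]),
                                  rng=rng))
            elif ls.kind == "a2c2f":
                mods.append(A2C2f(a["c1"], a["c2"], n=a["n"], a2=a["a2"],
                                  area=a.get("area", 1), rng=rng))
            elif ls.kind == "ema":
                mods.append(EMA(a["c"], a["g"], rng=rng))
            elif ls.kind == "upsample":
                mods.append(Upsample(a["scale"]))
            elif ls.kind == "concat":
                mods.append(None)
            elif ls.kind == "detect":
                mods.append(Detect(spec.nc, self._detect_channels(ls),
                                   spec.strides, rng=rng))
            else:
                raise ValueError(f"unknown layer kind {ls.kind}")
        self.layers = self.add_children([m for m in mods if m is not None])
        self._mods = mods

    def _detect_channels(self, ls: LayerSpec):
        chans = []
        for f in ls.frm:
            src = self.spec.layers[f]
            a = src.args
            chans.append(a.get("c2", a.get("c")))
        return tuple(chans)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[-1] % max(self.spec.strides) or x.shape[-2] % max(self.spec.strides):
            raise ValueError(
                f"image size {x.shape[-2:]} not divisible by stride {max(self.spec.strides)}"
            )
        outs: list = []
        for ls, mod in zip(self.spec.layers, self._mods):
            if ls.kind == "concat":
                y = concat([outs[f] for f in ls.frm], axis=1)
            elif ls.kind == "detect":
                y = mod([outs[f] for f in ls.frm])
            else:
                src = x if not ls.frm else outs[ls.frm[0]]
                y = mod(src)
            outs.append(y)
        return outs[-1]


# ------------------------------------------------------------------ profiling
def count_params(g: GraphSpec | DetectorModel) -> int:
    model = g if isinstance(g, DetectorModel) else DetectorModel(g)
    return model.param_count()


def profile_graph(g: GraphSpec | DetectorModel, imgsz: int = 640) -> ProfileReport:
    model = g if isinstance(g, DetectorModel) else DetectorModel(g)
    spec = model.spec
    sizes: list[tuple[int, int]] = []
    total = Profile()
    h = w = imgsz
    for ls, mod in zip(spec.layers, model._mods):
        if ls.kind == "concat":
            sizes.append(sizes[ls.frm[0]])
            continue
        if ls.kind == "detect":
            p3h, p3w = sizes[ls.frm[0]]
            pr, _ = mod.profile(p3h, p3w)
            total += pr
            sizes.append((p3h, p3w))
            continue
        ih, iw = (h, w) if not ls.frm else sizes[ls.frm[0]]
        pr, (oh, ow) = mod.profile(ih, iw)
        total += pr
        sizes.append((oh, ow))
    return ProfileReport(params=model.param_count(), flops=total.flops(),
                         imgsz=imgsz)


def count_flops(g: GraphSpec | DetectorModel, imgsz: int = 640) -> float:
    """Forward-pass GFLOPs (one decimal) at the given input size."""
    return profile_graph(g, imgsz).gflops


# ------------------------------------------------------------ detection sets
@dataclass
class DetectionSet:
    boxes: np.ndarray     # (n, 4) xyxy pixels
    scores: np.ndarray    # (n,)
    classes: np.ndarray   # (n,) int

    @classmethod
    def empty(cls):
        return cls(np.zeros((0, 4), np.float32), np.zeros(0, np.float32),
                   np.zeros(0, np.int64))

    def __len__(self):
        return len(self.scores)


def decode_predictions(raw_maps, strides=(8, 16, 32), conf_sigmoid=True):
    """Raw per-scale maps -> per-image (boxes xyxy, class scores).

    Returns (boxes (b, n, 4), scores (b, n, nc)) as plain ndarrays.
    """
    boxes_all, scores_all = [], []
    with no_grad():
        for raw, s in zip(raw_maps, strides):
            data = raw.data if isinstance(raw, Tensor) else raw
            b, ch, hh, ww = data.shape
            nc = ch - 4 * REG_MAX
            box_logits = data[:, : 4 * REG_MAX].reshape(b, 4, REG_MAX, hh * ww)
            box_logits = box_logits.transpose(0, 3, 1, 2)
            dist = dfl_expectation(Tensor(box_logits)).data      # (b, n, 4) ltrb
            ys, xs = np.meshgrid(np.arange(hh), np.arange(ww), indexing="ij")
            cx = (xs.ravel() + 0.5) * s
            cy = (ys.ravel() + 0.5) * s
            x1 = cx[None] - dist[..., 0] * s
            y1 = cy[None] - dist[..., 1] * s
            x2 = cx[None] + dist[..., 2] * s
            y2 = cy[None] + dist[..., 3] * s
            boxes_all.append(np.stack([x1, y1, x2, y2], axis=-1))
            cls = data[:, 4 * REG_MAX:].reshape(b, nc, hh * ww).transpose(0, 2, 1)
            if conf_sigmoid:
                cls = expit(cls)
            scores_all.append(cls)
    return np.concatenate(boxes_all, axis=1), np.concatenate(scores_all, axis=1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between xyxy box arrays (n,4) and (m,4)."""
    area_a = (a[:, 2] - a[:, 0]).clip(0) * (a[:, 3] - a[:, 1]).clip(0)
    area_b = (b[:, 2] - b[:, 0]).clip(0) * (b[:, 3] - b[:, 1]).clip(0)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = (rb - lt).clip(0)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms_postprocess(dets: DetectionSet, conf_thres: float = 0.25,
                    iou_thres: float = 0.45, max_det: int = 300,
                    img_wh: tuple[int, int] | None = None) -> DetectionSet:
    """Per-class greedy non-maximum suppression.

    Keeps the highest-scoring box, removes same-class overlaps above the IoU
    threshold; ties broken by lower box index.  Output sorted by descending
    score and clipped to the image bounds when given.
    """
    keep_mask = dets.scores >= conf_thres
    boxes, scores, classes = (dets.boxes[keep_mask], dets.scores[keep_mask],
                              dets.classes[keep_mask])
    order = np.lexsort((np.arange(len(scores)), -scores))
    boxes, scores, classes = boxes[order], scores[order], classes[order]
    keep: list[int] = []
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        cand = list(idx)
        while cand:
            best = cand.pop(0)
            keep.append(best)
            if not cand:
                break
            ious = box_iou_matrix(boxes[best:best + 1], boxes[cand])[0]
            cand = [c for c, i in zip(cand, ious) if i <= iou_thres]
    keep = sorted(keep, key=lambda i: (-scores[i], i))[:max_det]
    boxes, scores, classes = boxes[keep], scores[keep], classes[keep]
    if img_wh is not None:
        boxes[:, 0::2] = boxes[:, 0::2].clip(0, img_wh[0])
        boxes[:, 1::2] = boxes[:, 1::2].clip(0, img_wh[1])
    return DetectionSet(boxes, scores, classes)


def predict(model: DetectorModel, images: np.ndarray, conf_thres: float = 0.25,
            iou_thres: float = 0.45) -> list[DetectionSet]:
    """Full inference: forward, decode, NMS.  images: (b, 3, h, w) in [0,1]."""
    model.eval()
    with no_grad():
        raw = model(Tensor(images))
    boxes, scores = decode_predictions(raw, model.spec.strides)
    out = []
    h, w = images.shape[-2:]
    for bi in range(images.shape[0]):
        cls = scores[bi].argmax(axis=1)
        conf = scores[bi].max(axis=1)
        dets = DetectionSet(boxes[bi].astype(np.float32), conf.astype(np.float32),
                            cls.astype(np.int64))
        out.append(nms_postprocess(dets, conf_thres, iou_thres, img_wh=(w, h)))
    return out
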