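"""Training and evaluation loop (the workbench).

Standard single-stage detection training: task-aligned label assignment,
binary cross-entropy classification loss, distribution-focal box regression,
and a selectable IoU-family box loss (CIoU baseline, Wise-IoU v1/v3).  SGD
with momentum, linear warmup and cosine decay.  Everything is seeded and
single-threaded deterministic.

The desk-scale smoke protocol trains the full improved variant on a few
dozen synthetic scenes at reduced resolution; acceptance is qualitative
(loss decreases; the overfit train split reaches usable mAP), never a
real-data accuracy claim.
"""
from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .blocks import REG_MAX, dfl_expectation
from .detmetrics import GroundTruth, evaluate_detections
from .netgraph import (DetectionSet, DetectorModel, GraphSpec, VariantFlags,
                       box_iou_matrix, build_variant, predict)
from .nn.autograd import Tensor, concat, log, no_grad, softmax
from .wiou_losses import FocusingParams, OutlierState, ciou_t, iou_t, wiou_v1_t, wiou_v3_t


@dataclass
class TrainConfig:
    epochs: int = 100
    imgsz: int = 640
    batch: int = 8
    momentum: float = 0.937
    lr: float = 0.01
    weight_decay: float = 0.0005
    optimizer: str = "sgd"
    warmup_epochs: int = 3
    box_loss: str = "ciou"          # ciou | wiou_v1 | wiou_v3
    wiou_alpha: float = 1.9
    wiou_delta: float = 3.0
    wiou_momentum: float = 0.99
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "imgsz", "batch", "momentum", "lr", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:10]


@dataclass
class RunLog:
    config: dict
    variant: str
    seed: int
    profile: str
    epochs: list[dict] = field(default_factory=list)
    beta_stats: list[dict] = field(default_factory=list)

    def append(self, row: dict):
        self.epochs.append(row)

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "variant": self.variant, "seed": self.seed,
             "profile": self.profile, "epochs": self.epochs,
             "beta_stats": self.beta_stats}, indent=1))


# ----------------------------------------------------------------- assigner
def task_aligned_assign(scores, boxes, anchors, gt_boxes, gt_cls,
                        topk=10, alpha=0.5, beta=6.0):
    """Task-aligned assignment for one image (all arrays detached numpy).

    scores (A, nc) sigmoid scores; boxes (A, 4) xyxy; anchors (A, 2) centre
    pixels; gt_boxes (M, 4) xyxy.  Returns fg mask (A,), per-anchor gt index,
    and per-anchor class-target scores (A, nc).
    """
    A = anchors.shape[0]
    nc = scores.shape[1]
    tgt_scores = np.zeros((A, nc), np.float32)
    fg = np.zeros(A, bool)
    tgt_idx = np.zeros(A, np.int64)
    M = len(gt_cls)
    if M == 0:
        return fg, tgt_idx, tgt_scores
    inside = (
        (anchors[None, :, 0] > gt_boxes[:, None, 0])
        & (anchors[None, :, 0] < gt_boxes[:, None, 2])
        & (anchors[None, :, 1] > gt_boxes[:, None, 1])
        & (anchors[None, :, 1] < gt_boxes[:, None, 3])
    )
    iou = box_iou_matrix(gt_boxes, boxes)                       # (M, A)
    metric = scores[:, gt_cls].T ** alpha * iou ** beta
    metric = np.where(inside, metric, 0.0)
    cand = np.zeros_like(inside)
    k = min(topk, A)
    top = np.argpartition(-metric, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(M), k)
    cand[rows, top.ravel()] = metric[rows, top.ravel()] > 0
    # resolve collisions: anchor goes to the gt with the highest metric
    claimed = cand.any(axis=0)
    owner = np.where(claimed, np.argmax(np.where(cand, metric, -1.0), axis=0), 0)
    fg = claimed
    tgt_idx = owner
    # normalised target scores
    m_masked = np.where(cand, metric, 0.0)
    iou_masked = np.where(cand, iou, 0.0)
    mmax = m_masked.max(axis=1, keepdims=True) + 1e-9
    imax = iou_masked.max(axis=1, keepdims=True)
    norm = m_masked * imax / mmax                               # (M, A)
    for ai in np.flatnonzero(fg):
        gi = owner[ai]
        tgt_scores[ai, gt_cls[gi]] = min(1.0, norm[gi, ai])
    return fg, tgt_idx, tgt_scores


# -------------------------------------------------------------- loss pieces
def _bce_with_logits_sum(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable sum BCE-with-logits against constant targets."""
    from .nn.autograd import _make

    x = logits.data
    t = targets
    out = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def back(g):
        logits._accum(g * (expit(x) - t))

    s = _make(out, (logits,), back)
    return s.sum()


def make_anchors(imgsz: int, strides):
    anchors, stride_per = [], []
    for s in strides:
        n = imgsz // s
        ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        anchors.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
        stride_per.append(np.full(n * n, s, np.float32))
    return np.concatenate(anchors).astype(np.float32), np.concatenate(stride_per)


class DetectionLoss:
    """Composite loss: classification + box (CIoU / Wise-IoU) + DFL."""

    def __init__(self, cfg: TrainConfig, nc: int, strides=(8, 16, 32)):
        self.cfg = cfg
        self.nc = nc
        self.strides = strides
        self.anchors, self.stride_per = make_anchors(cfg.imgsz, strides)
        self.wiou_state = OutlierState(momentum=cfg.wiou_momentum)
        self.fp = FocusingParams(cfg.wiou_alpha, cfg.wiou_delta)
        self.last_beta: np.ndarray | None = None

    def _flatten(self, raw_maps):
        parts = []
        for raw in raw_maps:
            b, ch, hh, ww = raw.shape
            parts.append(raw.reshape(b, ch, hh * ww))
        return concat(parts, axis=2).transpose(0, 2, 1)   # (b, A, 4*REG_MAX+nc)

    def __call__(self, raw_maps, batch_labels, imgsz):
        """batch_labels: list (per image) of (cls, cx, cy, w, h) normalised."""
        flat = self._flatten(raw_maps)
        b = flat.shape[0]
        A = flat.shape[1]
        box_logits = flat[:, :, : 4 * REG_MAX].reshape(b, A, 4, REG_MAX)
        cls_logits = flat[:, :, 4 * REG_MAX:]
        dist = dfl_expectation(box_logits)                     # (b, A, 4) ltrb
        sp = self.stride_per[None, :, None]
        ax = self.anchors[None, :, 0]
        ay = self.anchors[None, :, 1]
        x1 = ax - dist[..., 0] * self.stride_per[None]
        y1 = ay - dist[..., 1] * self.stride_per[None]
        x2 = ax + dist[..., 2] * self.stride_per[None]
        y2 = ay + dist[..., 3] * self.stride_per[None]
        pred_cxcywh = concat(
            [((x1 + x2) * 0.5).reshape(b, A, 1), ((y1 + y2) * 0.5).reshape(b, A, 1),
             (x2 - x1).reshape(b, A, 1), (y2 - y1).reshape(b, A, 1)], axis=2)

        with no_grad():
            boxes_np = np.stack([x1.data, y1.data, x2.data, y2.data], axis=-1)
            scores_np = expit(cls_logits.data)

        tgt_scores = np.zeros((b, A, self.nc), np.float32)
        fg_all, gt_box_all = [], []
        for bi in range(b):
            labels = batch_labels[bi]
            if labels:
                arr = np.asarray(labels, np.float32)
                gt_cls = arr[:, 0].astype(np.int64)
                cx, cy, w, h = (arr[:, 1] * imgsz, arr[:, 2] * imgsz,
                                arr[:, 3] * imgsz, arr[:, 4] * imgsz)
                gt_xyxy = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
            else:
                gt_cls = np.zeros(0, np.int64)
                gt_xyxy = np.zeros((0, 4), np.float32)
            fg, tix, ts = task_aligned_assign(
                scores_np[bi], boxes_np[bi], self.anchors, gt_xyxy, gt_cls)
            tgt_scores[bi] = ts
            fg_all.append(fg)
            gt_box_all.append(gt_xyxy[tix[fg]] if fg.any() else np.zeros((0, 4), np.float32))

        ts_sum = max(float(tgt_scores.sum()), 1.0)
        loss_cls = _bce_with_logits_sum(cls_logits, tgt_scores) * (1.0 / ts_sum)

        bi_idx = np.concatenate([np.full(int(f.sum()), i) for i, f in enumerate(fg_all)]) \
            if any(f.any() for f in fg_all) else np.zeros(0, np.int64)
        ai_idx = np.concatenate([np.flatnonzero(f) for f in fg_all]) \
            if len(bi_idx) else np.zeros(0, np.int64)
        n_fg = len(bi_idx)
        if n_fg == 0:
            zero = Tensor(np.zeros(()))
            return loss_cls * self.cfg.cls_gain, {
                "cls": float(loss_cls.data), "box": 0.0, "dfl": 0.0, "n_fg": 0}

        gt_xyxy_fg = np.concatenate(gt_box_all).astype(np.float32)
        w_fg = np.concatenate([
            tgt_scores[i, f].sum(axis=1) for i, f in enumerate(fg_all) if f.any()
        ]).astype(np.float32)

        pred_fg = pred_cxcywh[bi_idx, ai_idx]                  # (n_fg, 4) via fancy index
        gt_cxcywh = np.stack([
            (gt_xyxy_fg[:, 0] + gt_xyxy_fg[:, 2]) / 2,
            (gt_xyxy_fg[:, 1] + gt_xyxy_fg[:, 3]) / 2,
            gt_xyxy_fg[:, 2] - gt_xyxy_fg[:, 0],
            gt_xyxy_fg[:, 3] - gt_xyxy_fg[:, 1]], axis=1).astype(np.float32)
        gt_t = Tensor(gt_cxcywh)

        if self.cfg.box_loss == "wiou_v3":
            per_box, self.wiou_state = wiou_v3_t(pred_fg, gt_t, self.wiou_state,
                                                 self.fp, weights=w_fg)
            with no_grad():
                liou = 1.0 - iou_t(pred_fg, gt_t).data
                self.last_beta = liou / max(self.wiou_state.mean, 1e-9)
        elif self.cfg.box_loss == "wiou_v1":
            per_box = wiou_v1_t(pred_fg, gt_t)
        else:
            per_box = ciou_t(pred_fg, gt_t)
        loss_box = (per_box * Tensor(w_fg)).sum() * (1.0 / ts_sum)

        # distribution-focal loss on the two neighbouring bins
        tgt_ltrb = np.stack([
            (self.anchors[ai_idx, 0] - gt_xyxy_fg[:, 0]),
            (self.anchors[ai_idx, 1] - gt_xyxy_fg[:, 1]),
            (gt_xyxy_fg[:, 2] - self.anchors[ai_idx, 0]),
            (gt_xyxy_fg[:, 3] - self.anchors[ai_idx, 1])], axis=1)
        tgt_ltrb = np.clip(tgt_ltrb / self.stride_per[ai_idx][:, None], 0, REG_MAX - 1.01)
        lo = np.floor(tgt_ltrb).astype(np.int64)
        hi = lo + 1
        w_hi = tgt_ltrb - lo
        w_lo = 1.0 - w_hi
        logp = log(softmax(box_logits[bi_idx, ai_idx], axis=-1) + 1e-9)  # (n_fg,4,REG_MAX)
        oh = np.zeros((n_fg, 4, REG_MAX), np.float32)
        rows = np.repeat(np.arange(n_fg), 4)
        cols = np.tile(np.arange(4), n_fg)
        oh[rows, cols, lo.ravel()] += w_lo.ravel()
        oh[rows, cols, hi.ravel()] += w_hi.ravel()
        dfl_per = -(logp * Tensor(oh)).sum(axis=(1, 2)) * 0.25
        loss_dfl = (dfl_per * Tensor(w_fg)).sum() * (1.0 / ts_sum)

        total = (self.cfg.box_gain * loss_box + self.cfg.cls_gain * loss_cls
                 + self.cfg.dfl_gain * loss_dfl)
        return total, {"cls": float(loss_cls.data), "box": float(loss_box.data),
                       "dfl": float(loss_dfl.data), "n_fg": n_fg}


# ---------------------------------------------------------------- optimiser
class SGD:
    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:   # no decay on norms/biases
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def lr_at(cfg: TrainConfig, epoch: int, step: int, steps_per_epoch: int) -> float:
    t = epoch + step / max(steps_per_epoch, 1)
    if t < cfg.warmup_epochs:
        return cfg.lr * (0.1 + 0.9 * t / cfg.warmup_epochs)
    frac = (t - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs, 1e-9)
    return cfg.lr * (0.01 + 0.99 * 0.5 * (1 + math.cos(math.pi * min(frac, 1.0))))


# ------------------------------------------------------------------ training
def train(cfg: TrainConfig, flags: VariantFlags, images, labels,
          out_dir=None, verbose: bool = False) -> tuple[RunLog, DetectorModel]:
    """Train a variant on in-memory data.

    images: list of (3, H, W) float arrays in [0,1]; labels: per-image YOLO
    tuples.  When the variant requests the Wise-IoU loss the box-loss choice
    in the config is overridden accordingly.
    """
    if flags.wiou and cfg.box_loss == "ciou":
        cfg = TrainConfig(**{**asdict(cfg), "box_loss": "wiou_v3"})
    rng = np.random.default_rng(cfg.seed)
    spec = build_variant(flags, nc=5)
    model = DetectorModel(spec, seed=cfg.seed)
    crit = DetectionLoss(cfg, nc=spec.nc)
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    from .netgraph import profile_graph

    logrec = RunLog(config=asdict(cfg), variant=flags.tag(), seed=cfg.seed,
                    profile=str(profile_graph(spec)))
    n = len(images)
    order = np.arange(n)
    steps_per_epoch = max(1, n // cfg.batch)
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        model.train()
        tot = {"cls": 0.0, "box": 0.0, "dfl": 0.0}
        betas = []
        t0 = time.time()
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch:(step + 1) * cfg.batch]
            xb = np.stack([images[i] for i in idx]).astype(np.float32)
            yb = [labels[i] for i in idx]
            opt.lr = lr_at(cfg, epoch, step, steps_per_epoch)
            raw = model(Tensor(xb))
            loss, parts = crit(raw, yb, cfg.imgsz)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch} step {step}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in tot:
                tot[k] += parts[k]
            if crit.last_beta is not None and len(crit.last_beta):
                betas.append(crit.last_beta.mean())
        row = {"epoch": epoch, "lr": opt.lr,
               **{k: v / steps_per_epoch for k, v in tot.items()},
               "time": time.time() - t0}
        row["total"] = (cfg.box_gain * row["box"] + cfg.cls_gain * row["cls"]
                        + cfg.dfl_gain * row["dfl"])
        logrec.append(row)
        if betas:
            logrec.beta_stats.append({"epoch": epoch, "beta_mean": float(np.mean(betas))})
        if verbose:
            print(f"epoch {epoch:3d} loss {row['total']:.4f} "
                  f"(box {row['box']:.3f} cls {row['cls']:.3f} dfl {row['dfl']:.3f}) "
                  f"lr {opt.lr:.4f} {row['time']:.1f}s")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_weights(model, out_dir / "weights.npz")
        logrec.save(out_dir / "runlog.json")
    return logrec, model


def save_weights(model: DetectorModel, path):
    np.savez(path, **model.state_arrays())


def load_weights(model: DetectorModel, path):
    with np.load(path) as data:
        model.load_state_arrays(dict(data))
    return model


def evaluate(model: DetectorModel, images, labels, conf_thres=0.001,
             iou_thres=0.45, batch: int = 8) -> dict:
    """Forward + NMS + metrics over an image list."""
    if len(images) == 0:
        raise ValueError("empty evaluation split")
    model.eval()
    h, w = images[0].shape[-2:]
    preds, truths = [], []
    for i in range(0, len(images), batch):
        xb = np.stack(images[i:i + batch]).astype(np.float32)
        preds.extend(predict(model, xb, conf_thres, iou_thres))
    for lab in labels:
        if lab:
            arr = np.asarray(lab, np.float32)
            cx, cy, bw, bh = arr[:, 1] * w, arr[:, 2] * h, arr[:, 3] * w, arr[:, 4] * h
            boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)
            truths.append(GroundTruth(boxes, arr[:, 0].astype(np.int64)))
        else:
            truths.append(GroundTruth(np.zeros((0, 4), np.float32), np.zeros(0, np.int64)))
    return evaluate_detections(preds, truths, nc=5)
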