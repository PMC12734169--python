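"""Bounding-box regression losses: IoU, Wise-IoU v1 and Wise-IoU v3.

Boxes are centre-format ``(cx, cy, w, h)``; geometry is continuous (no
pixel quantisation).  The Wise-IoU family is built from two pieces:

* an attention term ``R_WIoU = exp(d^2 / D^2)`` where ``d`` is the
  centre-to-centre distance of the predicted and true boxes and ``D`` the
  diagonal of their smallest enclosing box — the enclosure size is
  *detached* from the gradient so it scales but never steers the update;
* the plain IoU loss ``L_IoU = 1 - IoU``.

``L_WIoUv1 = R_WIoU * L_IoU``, and v3 multiplies it by a non-monotonic
focusing coefficient ``gamma(beta) = beta / (delta * alpha^(beta-delta))``
driven by the outlier degree ``beta = L_IoU* / L_IoU_bar``: the ratio of the
current (detached) IoU loss to an exponential moving average of past IoU
losses.  Ordinary-quality anchors (``beta`` near ``delta``) get gain near 1,
pristine anchors are de-emphasised, and genuinely bad anchors — typically
mislabelled or background-heavy boxes such as leafminer-trail annotations —
are suppressed because ``gamma -> 0`` as ``beta -> inf`` whenever
``alpha > 1``.  Because the running mean drifts with training, the quality
classification is dynamic rather than tied to an absolute threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, as_tensor, clip, exp, maximum, minimum, no_grad


class InvalidBoxError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Box:
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box sides must be positive, got w={self.w} h={self.h}")

    @property
    def x1(self):
        return self.cx - self.w / 2

    @property
    def y1(self):
        return self.cy - self.h / 2

    @property
    def x2(self):
        return self.cx + self.w / 2

    @property
    def y2(self):
        return self.cy + self.h / 2


@dataclass(frozen=True)
class BoxPair:
    pred: Box
    gt: Box

    @property
    def wg(self) -> float:
        return max(self.pred.x2, self.gt.x2) - min(self.pred.x1, self.gt.x1)

    @property
    def hg(self) -> float:
        return max(self.pred.y2, self.gt.y2) - min(self.pred.y1, self.gt.y1)


@dataclass(frozen=True)
class FocusingParams:
    alpha: float = 1.9
    delta: float = 3.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if self.delta <= 0:
            raise ConfigError(f"delta must be positive, got {self.delta}")

    @property
    def beta_argmax(self) -> float:
        """beta maximising gamma; defined for alpha > 1."""
        return 1.0 / math.log(self.alpha)


@dataclass
class OutlierState:
    """Exponential moving average of the IoU loss, updated outside the
    gradient path.  Warm-started at the first observed batch mean."""

    momentum: float = 0.99
    mean: float = 0.0
    initialized: bool = False

    def update(self, batch_mean_liou: float) -> "OutlierState":
        if not self.initialized:
            return OutlierState(self.momentum, float(batch_mean_liou), True)
        new = self.momentum * self.mean + (1.0 - self.momentum) * float(batch_mean_liou)
        return OutlierState(self.momentum, new, True)


# ----------------------------------------------------------- tensor kernels
def _corners(boxes: Tensor):
    cx, cy = boxes[..., 0], boxes[..., 1]
    w, h = boxes[..., 2], boxes[..., 3]
    return cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5


def iou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Elementwise IoU of centre-format box tensors shaped (..., 4)."""
    px1, py1, px2, py2 = _corners(as_tensor(pred))
    gx1, gy1, gx2, gy2 = _corners(as_tensor(gt))
    iw = clip(minimum(px2, gx2) - maximum(px1, gx1), 0.0, None)
    ih = clip(minimum(py2, gy2) - maximum(py1, gy1), 0.0, None)
    inter = iw * ih
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    return inter / (union + 1e-9)


def rwiou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """exp(centre distance^2 / enclosure diagonal^2), diagonal detached."""
    pred, gt = as_tensor(pred), as_tensor(gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    wg = maximum(px2, gx2) - minimum(px1, gx1)
    hg = maximum(py2, gy2) - minimum(py1, gy1)
    d2 = (pred[..., 0] - gt[..., 0]) ** 2.0 + (pred[..., 1] - gt[..., 1]) ** 2.0
    diag2 = (wg * wg + hg * hg).detach()  # the superscript-star separation
    return exp(d2 / (diag2 + 1e-9))


def wiou_v1_t(pred: Tensor, gt: Tensor) -> Tensor:
    return rwiou_t(pred, gt) * (1.0 - iou_t(pred, gt))


def ciou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Complete-IoU loss term (the baseline's box loss), returned as 1 - CIoU."""
    from .nn.autograd import arctan

    pred, gt = as_tensor(pred), as_tensor(gt)
    iou = iou_t(pred, gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    wg = maximum(px2, gx2) - minimum(px1, gx1)
    hg = maximum(py2, gy2) - minimum(py1, gy1)
    d2 = (pred[..., 0] - gt[..., 0]) ** 2.0 + (pred[..., 1] - gt[..., 1]) ** 2.0
    diag2 = wg * wg + hg * hg + 1e-9
    v = (4.0 / math.pi ** 2) * (
        arctan(gt[..., 2] / (gt[..., 3] + 1e-9)) - arctan(pred[..., 2] / (pred[..., 3] + 1e-9))
    ) ** 2.0
    with no_grad():
        alpha = v.data / (1.0 - iou.data + v.data + 1e-9)
    return 1.0 - iou + d2 / diag2 + Tensor(alpha) * v


# ------------------------------------------------------------- scalar API
def iou(pair: BoxPair) -> float:
    return float(iou_t(Tensor([pair.pred.cx, pair.pred.cy, pair.pred.w, pair.pred.h]),
                       Tensor([pair.gt.cx, pair.gt.cy, pair.gt.w, pair.gt.h])).data)


def rwiou(pair: BoxPair) -> float:
    if pair.wg <= 0 or pair.hg <= 0:
        raise InvalidBoxError("degenerate enclosing box")
    return float(rwiou_t(Tensor([pair.pred.cx, pair.pred.cy, pair.pred.w, pair.pred.h]),
                         Tensor([pair.gt.cx, pair.gt.cy, pair.gt.w, pair.gt.h])).data)


def wiou_v1(pair: BoxPair) -> float:
    return rwiou(pair) * (1.0 - iou(pair))


def focusing_gamma(beta: float, fp: FocusingParams = FocusingParams()) -> float:
    """gamma = beta / (delta * alpha^(beta - delta)); equals 1 at beta = delta."""
    if beta < 0:
        raise InvalidBoxError(f"outlier degree must be nonnegative, got {beta}")
    return float(beta / (fp.delta * fp.alpha ** (beta - fp.delta)))


def wiou_v3(pair: BoxPair, state: OutlierState,
            fp: FocusingParams = FocusingParams()) -> tuple[float, OutlierState]:
    """Single-pair Wise-IoU v3: loss value plus the advanced running state."""
    liou = 1.0 - iou(pair)
    mean = liou if not state.initialized else state.mean
    beta = liou / max(mean, 1e-9)
    loss = focusing_gamma(beta, fp) * wiou_v1(pair)
    return loss, state.update(liou)


def wiou_v3_t(pred: Tensor, gt: Tensor, state: OutlierState,
              fp: FocusingParams = FocusingParams(),
              weights: np.ndarray | None = None) -> tuple[Tensor, OutlierState]:
    """Vectorised Wise-IoU v3 over assigned anchors.

    Per-anchor beta uses the per-anchor detached IoU loss against the global
    running mean; the state advances with the (optionally weighted) batch
    mean *after* the loss is formed.  Returns (per-anchor loss tensor, new
    state).
    """
    liou = 1.0 - iou_t(pred, gt)
    with no_grad():
        liou_np = liou.data
        if weights is not None and weights.sum() > 0:
            batch_mean = float((liou_np * weights).sum() / weights.sum())
        else:
            batch_mean = float(liou_np.mean()) if liou_np.size else 0.0
        mean = batch_mean if not state.initialized else state.mean
        beta = liou_np / max(mean, 1e-9)
        gamma = beta / (fp.delta * fp.alpha ** (beta - fp.delta))
    loss = Tensor(gamma.astype(np.float32)) * rwiou_t(pred, gt) * liou
    return loss, state.update(batch_mean)
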