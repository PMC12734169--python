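"""Detection evaluation: precision, recall, F1, per-class AP, mAP50,
mAP50-95 and the confusion matrix.

Matching is the standard protocol: within a class, detections are taken in
descending confidence and greedily matched one-to-one to the unmatched
ground-truth box of highest IoU, requiring IoU at or above the threshold.
AP integrates the precision-recall curve with the 101-point monotone
envelope; mAP is the unweighted mean over classes; mAP50-95 averages the
IoU thresholds 0.50:0.05:0.95.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .netgraph import DetectionSet, box_iou_matrix


@dataclass
class MatchTally:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("tallies must be nonnegative")

    def __add__(self, other):
        return MatchTally(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.recall) < -1e-9):
            raise ValueError("recall must be nondecreasing along the sweep")


@dataclass
class GroundTruth:
    boxes: np.ndarray    # (n, 4) xyxy
    classes: np.ndarray  # (n,)


def _match_one_image(det: DetectionSet, gt: GroundTruth, iou_thr: float):
    """Greedy per-class matching; returns (tp_flags over detections sorted
    by confidence within class order preserved, matched gt indices)."""
    order = np.argsort(-det.scores, kind="stable")
    matched_gt: set[int] = set()
    tp_flags = np.zeros(len(det.scores), dtype=bool)
    match_of = -np.ones(len(det.scores), dtype=int)
    for di in order:
        cls = det.classes[di]
        cand = [
            gi for gi in range(len(gt.classes))
            if gt.classes[gi] == cls and gi not in matched_gt
        ]
        if not cand:
            continue
        ious = box_iou_matrix(det.boxes[di:di + 1], gt.boxes[cand])[0]
        best = int(np.argmax(ious))
        if ious[best] >= iou_thr:
            matched_gt.add(cand[best])
            tp_flags[di] = True
            match_of[di] = cand[best]
    return tp_flags, match_of


def match_detections(preds: list[DetectionSet], truths: list[GroundTruth],
                     iou_thr: float = 0.5, nc: int | None = None) -> dict[int, MatchTally]:
    """Per-class TP/FP/FN tallies over an image set."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth image sets differ in length")
    classes = set()
    for t in truths:
        classes.update(int(c) for c in t.classes)
    for d in preds:
        classes.update(int(c) for c in d.classes)
    if nc is not None:
        classes.update(range(nc))
    tallies = {c: MatchTally() for c in sorted(classes)}
    for det, gt in zip(preds, truths):
        tp_flags, _ = _match_one_image(det, gt, iou_thr)
        for c in tallies:
            dm = det.classes == c
            tp = int(tp_flags[dm].sum())
            tallies[c] = tallies[c] + MatchTally(
                tp=tp, fp=int(dm.sum()) - tp,
                fn=int((gt.classes == c).sum()) - tp,
            )
    return tallies


def precision_recall(t: MatchTally) -> tuple[float, float]:
    """(P, R) in percent; zero denominators give 0."""
    p = 100.0 * t.tp / (t.tp + t.fp) if t.tp + t.fp else 0.0
    r = 100.0 * t.tp / (t.tp + t.fn) if t.tp + t.fn else 0.0
    return p, r


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (same percent scale)."""
    return 2.0 * p * r / (p + r) if p + r else 0.0


def pr_curve(scores: np.ndarray, tp_flags: np.ndarray, n_gt: int) -> PRCurve:
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(tp_flags[order])
    fp = np.cumsum(~tp_flags[order])
    recall = tp / max(n_gt, 1)
    precision = tp / np.maximum(tp + fp, 1e-12)
    return PRCurve(recall.astype(float), precision.astype(float))


def average_precision(curve: PRCurve) -> float:
    """Area under the interpolated PR curve (101-point monotone envelope)."""
    if curve.recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [1.0]])
    p = np.concatenate([[1.0], curve.precision, [0.0]])
    # monotone envelope from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(r, grid, side="left")
    return float(p[np.minimum(idx, p.size - 1)].mean())


def class_ap(preds: list[DetectionSet], truths: list[GroundTruth], cls: int,
             iou_thr: float = 0.5) -> float:
    scores, flags = [], []
    n_gt = 0
    for det, gt in zip(preds, truths):
        tp_flags, _ = _match_one_image(det, gt, iou_thr)
        dm = det.classes == cls
        scores.append(det.scores[dm])
        flags.append(tp_flags[dm])
        n_gt += int((gt.classes == cls).sum())
    scores = np.concatenate(scores) if scores else np.zeros(0)
    flags = np.concatenate(flags) if flags else np.zeros(0, bool)
    if n_gt == 0:
        return 0.0
    if scores.size == 0:
        return 0.0
    return average_precision(pr_curve(scores, flags, n_gt))


def map50(per_class_aps) -> float:
    """Unweighted mean of per-class APs (values on whatever scale given)."""
    aps = np.asarray(list(per_class_aps), dtype=float)
    if aps.size == 0:
        raise ValueError("need at least one class AP")
    return float(aps.mean())


def evaluate_detections(preds: list[DetectionSet], truths: list[GroundTruth],
                        nc: int, iou_thr: float = 0.5) -> dict:
    """Full report: per-class AP50, mAP50, mAP50-95, aggregate P/R/F1."""
    aps50 = [class_ap(preds, truths, c, 0.5) for c in range(nc)]
    aps_all = {
        round(t, 2): [class_ap(preds, truths, c, t) for c in range(nc)]
        for t in np.arange(0.5, 0.96, 0.05)
    }
    tallies = match_detections(preds, truths, iou_thr, nc=nc)
    agg = MatchTally()
    for t in tallies.values():
        agg = agg + t
    p, r = precision_recall(agg)
    return {
        "ap50_per_class": aps50,
        "map50": map50(aps50),
        "map50_95": float(np.mean([np.mean(v) for v in aps_all.values()])),
        "precision": p,
        "recall": r,
        "f1": f1(p, r),
        "tally": agg,
    }


def confusion_matrix(preds: list[DetectionSet], truths: list[GroundTruth],
                     nc: int, conf_thr: float = 0.25, iou_thr: float = 0.45) -> np.ndarray:
    """(nc+1)x(nc+1) counts; rows = predicted class (+background),
    columns = true class (+background).  Matching here is class-agnostic so
    cross-class confusions land off-diagonal."""
    mat = np.zeros((nc + 1, nc + 1), dtype=int)
    for det, gt in zip(preds, truths):
        keep = det.scores >= conf_thr
        boxes, classes, scores = det.boxes[keep], det.classes[keep], det.scores[keep]
        order = np.argsort(-scores, kind="stable")
        matched_gt: set[int] = set()
        for di in order:
            cand = [gi for gi in range(len(gt.classes)) if gi not in matched_gt]
            if cand:
                ious = box_iou_matrix(boxes[di:di + 1], gt.boxes[cand])[0]
                best = int(np.argmax(ious))
                if ious[best] >= iou_thr:
                    gi = cand[best]
                    matched_gt.add(gi)
                    mat[classes[di], gt.classes[gi]] += 1
                    continue
            mat[classes[di], nc] += 1          # prediction on background
        for gi in range(len(gt.classes)):
            if gi not in matched_gt:
                mat[nc, gt.classes[gi]] += 1   # missed truth
    return mat


def write_ap_csv(path, class_names, aps50):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "ap50"])
        for name, ap in zip(class_names, aps50):
            w.writerow([name, f"{100 * ap:.1f}"])
        w.writerow(["mAP50", f"{100 * float(np.mean(aps50)):.2f}"])


def write_confusion_csv(path, class_names, mat):
    names = list(class_names) + ["background"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pred\\true"] + names)
        for name, row in zip(names, mat):
            w.writerow([name] + list(map(int, row)))
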