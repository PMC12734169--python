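"""Evaluation formulas: tallies, P/R/F1, AP against enumeration oracles,
mAP identities, and the confusion matrix."""
import numpy as np
import pytest

from pestdet.detmetrics import (GroundTruth, MatchTally, PRCurve,
                                average_precision, class_ap, confusion_matrix,
                                f1, map50, match_detections, pr_curve,
                                precision_recall)
from pestdet.netgraph import DetectionSet


def ds(boxes, scores, classes):
    return DetectionSet(np.asarray(boxes, np.float32).reshape(-1, 4),
                        np.asarray(scores, np.float32),
                        np.asarray(classes, np.int64))


def gt(boxes, classes):
    return GroundTruth(np.asarray(boxes, np.float32).reshape(-1, 4),
                       np.asarray(classes, np.int64))


class TestMatching:
    def test_perfect_predictions(self):
        boxes = [[0, 0, 5, 5], [10, 10, 15, 16]]
        t = match_detections([ds(boxes, [0.9, 0.8], [0, 1])],
                             [gt(boxes, [0, 1])], 0.5)
        assert t[0] == MatchTally(1, 0, 0) and t[1] == MatchTally(1, 0, 0)

    def test_no_predictions_all_missed(self):
        t = match_detections([ds(np.zeros((0, 4)), [], [])],
                             [gt([[0, 0, 5, 5]], [2])], 0.5)
        assert t[2] == MatchTally(0, 0, 1)

    def test_one_to_one_greedy(self):
        # two detections on one truth: the higher-confidence one matches
        t = match_detections(
            [ds([[0, 0, 5, 5], [0.2, 0, 5.2, 5]], [0.7, 0.9], [0, 0])],
            [gt([[0, 0, 5, 5]], [0])], 0.5)
        assert t[0] == MatchTally(1, 1, 0)

    def test_matches_bruteforce_assignment(self, rng):
        """With well-separated IoUs the greedy tally equals the exhaustive
        best one-to-one assignment."""
        import itertools

        for trial in range(20):
            r = np.random.default_rng(trial)
            n_gt, n_det = r.integers(1, 4), r.integers(1, 4)
            centers = r.uniform(10, 90, (n_gt, 2))
            gt_boxes = np.hstack([centers - 4, centers + 4])
            det_boxes, det_conf = [], []
            for i in range(n_det):
                if i < n_gt:
                    jitter = r.uniform(-1.5, 1.5, 2)
                    det_boxes.append(np.hstack([centers[i] - 4 + jitter,
                                                centers[i] + 4 + jitter]))
                else:
                    c = r.uniform(110, 150, 2)
                    det_boxes.append(np.hstack([c - 4, c + 4]))
                det_conf.append(r.uniform(0.2, 1.0))
            det = ds(np.array(det_boxes), det_conf, np.zeros(n_det, int))
            truth = gt(gt_boxes, np.zeros(n_gt, int))
            tal = match_detections([det], [truth], 0.5)[0]
            from pestdet.netgraph import box_iou_matrix

            iou = box_iou_matrix(det.boxes, truth.boxes)
            k = int(min(n_det, n_gt))
            best_tp = 0
            for gts in itertools.combinations(range(int(n_gt)), k):
                for dets in itertools.permutations(range(int(n_det)), k):
                    tp = sum(iou[d, g] >= 0.5 for g, d in zip(gts, dets))
                    best_tp = max(best_tp, tp)
            assert tal.tp == best_tp


class TestPRF:
    def test_eight_two_two(self):
        p, r = precision_recall(MatchTally(8, 2, 2))
        assert (p, r) == (80.0, 80.0)
        assert f1(p, r) == pytest.approx(80.0)

    def test_perfect(self):
        p, r = precision_recall(MatchTally(5, 0, 0))
        assert (p, r) == (100.0, 100.0)

    def test_all_false_positive(self):
        p, r = precision_recall(MatchTally(0, 3, 0))
        assert p == 0.0

    def test_zero_denominators(self):
        assert precision_recall(MatchTally(0, 0, 0)) == (0.0, 0.0)
        assert f1(0.0, 0.0) == 0.0

    def test_f1_examples(self):
        assert f1(100.0, 0.0) == 0.0
        assert f1(86.76, 79.94) == pytest.approx(83.21, abs=0.01)

    def test_f1_below_arithmetic_mean(self, rng):
        for _ in range(100):
            p, r = rng.uniform(0, 100, 2)
            assert f1(p, r) <= (p + r) / 2 + 1e-9

    def test_negative_tally_rejected(self):
        with pytest.raises(ValueError):
            MatchTally(-1, 0, 0)


class TestAP:
    def test_perfect_detector_ap_one(self):
        truths = [gt([[0, 0, 5, 5], [20, 20, 30, 30]], [0, 0])]
        preds = [ds([[0, 0, 5, 5], [20, 20, 30, 30]], [0.9, 0.8], [0, 0])]
        assert class_ap(preds, truths, 0) == pytest.approx(1.0)

    def test_toy_interleaved_fp_matches_enumeration(self):
        """Three detections (TP, FP, TP by confidence order) over two truths:
        the 101-point envelope area is computed by hand.

        sweep: p = 1/1, 1/2, 2/3; r = 1/2, 1/2, 1.
        envelope: precision 1.0 for r <= 0.5, 2/3 for r <= 1.
        AP = (51 * 1.0 + 50 * 2/3) / 101.
        """
        truths = [gt([[0, 0, 4, 4], [10, 10, 14, 14]], [0, 0])]
        preds = [ds([[0, 0, 4, 4], [40, 40, 44, 44], [10, 10, 14, 14]],
                    [0.9, 0.8, 0.7], [0, 0, 0])]
        expect = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert class_ap(preds, truths, 0) == pytest.approx(expect, abs=1e-9)

    def test_ap_bounded(self, rng):
        curve = pr_curve(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20) > 0.5, 10)
        assert 0.0 <= average_precision(curve) <= 1.0

    def test_removing_tp_never_raises_ap(self):
        truths = [gt([[0, 0, 4, 4], [10, 10, 14, 14]], [0, 0])]
        full = [ds([[0, 0, 4, 4], [10, 10, 14, 14], [40, 40, 44, 44]],
                   [0.9, 0.7, 0.8], [0, 0, 0])]
        fewer = [ds([[0, 0, 4, 4], [40, 40, 44, 44]], [0.9, 0.8], [0, 0])]
        assert class_ap(fewer, truths, 0) <= class_ap(full, truths, 0)

    def test_empty_curve_zero(self):
        assert average_precision(PRCurve(np.zeros(0), np.zeros(0))) == 0.0

    def test_recall_monotone_enforced(self):
        with pytest.raises(ValueError):
            PRCurve(np.array([0.5, 0.2]), np.array([1.0, 1.0]))


class TestMAP:
    def test_map_is_unweighted_mean(self, rng):
        aps = rng.uniform(0, 1, 5)
        assert map50(aps) == pytest.approx(aps.mean(), abs=1e-12)

    def test_improved_model_class_aps_average(self):
        # the five per-class AP50 values of the fully improved detector
        assert map50([79.4, 62.8, 98.9, 98.9, 85.3]) == pytest.approx(85.06)


class TestConfusion:
    def test_perfect_diagonal(self):
        boxes = [[0, 0, 5, 5], [10, 10, 15, 15]]
        mat = confusion_matrix([ds(boxes, [0.9, 0.9], [0, 1])],
                               [gt(boxes, [0, 1])], nc=3)
        assert mat[0, 0] == 1 and mat[1, 1] == 1
        assert mat.sum() == 2

    def test_no_detections_background_row(self):
        mat = confusion_matrix([ds(np.zeros((0, 4)), [], [])],
                               [gt([[0, 0, 5, 5]], [2])], nc=3)
        assert mat[3, 2] == 1 and mat.sum() == 1

    def test_class_swap_lands_off_diagonal(self):
        boxes = [[0, 0, 5, 5], [10, 10, 15, 15]]
        mat = confusion_matrix([ds(boxes, [0.9, 0.9], [1, 0])],
                               [gt(boxes, [0, 1])], nc=2)
        assert mat[1, 0] == 1 and mat[0, 1] == 1
        assert mat[0, 0] == mat[1, 1] == 0

    def test_total_mass_accounts_everything(self, rng):
        preds = [ds([[0, 0, 5, 5]], [0.9], [0])]
        truths = [gt([[0, 0, 5, 5], [20, 20, 25, 25]], [0, 1])]
        mat = confusion_matrix(preds, truths, nc=2)
        assert mat.sum() == 2  # one match + one missed truth
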