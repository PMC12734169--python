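"""Graph assembly, profiling determinism, ablation deltas, decoding and NMS."""
import numpy as np
import pytest

from pestdet.netgraph import (DetectionSet, DetectorModel, VariantFlags,
                              box_iou_matrix, build_variant, count_flops,
                              count_params, nms_postprocess, predict,
                              profile_graph)
from pestdet.nn import Tensor, no_grad


@pytest.fixture(scope="module")
def profiles():
    out = {}
    for tag, fl in {
        "baseline": VariantFlags(),
        "ema": VariantFlags(ema=True),
        "fusion": VariantFlags(fusion=True),
        "wiou": VariantFlags(wiou=True),
        "c3k2b": VariantFlags(c3k2b=True),
        "full": VariantFlags.full(),
    }.items():
        out[tag] = profile_graph(build_variant(fl, nc=5))
    return out


class TestGraphs:
    def test_dag_and_single_detect(self):
        for fl in (VariantFlags(), VariantFlags.full()):
            build_variant(fl, nc=5).validate()

    def test_all_flag_combinations_buildable(self):
        import itertools

        for bits in itertools.product((False, True), repeat=4):
            spec = build_variant(VariantFlags(*bits), nc=5)
            spec.validate()

    def test_nc_changes_head_only(self):
        p1 = count_params(build_variant(VariantFlags(), nc=1))
        p5 = count_params(build_variant(VariantFlags(), nc=5))
        # only the three final 1x1 class convs change: (64+1)*(5-1)*3
        assert p5 - p1 == 3 * (64 + 1) * 4

    def test_invalid_nc(self):
        with pytest.raises(ValueError):
            build_variant(VariantFlags(), nc=0)


class TestProfiles:
    def test_deterministic(self):
        a = profile_graph(build_variant(VariantFlags.full(), nc=5))
        b = profile_graph(build_variant(VariantFlags.full(), nc=5))
        assert (a.params, a.flops) == (b.params, b.flops)

    def test_ema_adds_parameters(self, profiles):
        assert profiles["ema"].params > profiles["baseline"].params

    def test_c3k2b_removes_parameters(self, profiles):
        assert profiles["c3k2b"].params < profiles["baseline"].params

    def test_wiou_changes_nothing(self, profiles):
        assert profiles["wiou"].params == profiles["baseline"].params
        assert profiles["wiou"].flops == profiles["baseline"].flops

    def test_fusion_raises_flops_lowers_params(self, profiles):
        assert profiles["fusion"].flops > profiles["baseline"].flops
        assert profiles["fusion"].params < profiles["baseline"].params

    def test_single_conv_param_formula(self):
        from pestdet.nn.layers import Conv

        conv = Conv(16, 32, 3, bn=False)
        assert conv.param_count() == 3 * 3 * 16 * 32 + 32

    def test_single_conv_flop_formula(self):
        from pestdet.nn.layers import Conv

        conv = Conv(16, 32, 3, s=1, bn=False, act="none")
        pr, _ = conv.profile(64, 64)
        assert pr.flops() == 2 * 3 * 3 * 16 * 32 * 64 * 64


class TestForward:
    def test_three_scales_and_batch_dim(self):
        model = DetectorModel(build_variant(VariantFlags(), nc=5), seed=0).eval()
        x = np.random.default_rng(0).random((1, 3, 160, 160), dtype=np.float32)
        with no_grad():
            outs = model(Tensor(x))
        assert [o.shape for o in outs] == [
            (1, 69, 20, 20), (1, 69, 10, 10), (1, 69, 5, 5)]
        with no_grad():
            outs2 = model(Tensor(np.concatenate([x, x])))
        assert outs2[0].shape[0] == 2
        # same image -> same maps regardless of batch context (eval mode)
        assert np.allclose(outs2[0].data[0], outs[0].data[0], atol=1e-5)

    def test_anchor_count_matches_stride_sum(self):
        imgsz = 160
        expect = sum((imgsz // s) ** 2 for s in (8, 16, 32))
        model = DetectorModel(build_variant(VariantFlags(), nc=5), seed=0).eval()
        from pestdet.netgraph import decode_predictions

        with no_grad():
            raw = model(Tensor(np.zeros((1, 3, imgsz, imgsz), np.float32)))
        boxes, scores = decode_predictions(raw)
        assert boxes.shape[1] == expect == 525

    def test_indivisible_size_rejected(self):
        model = DetectorModel(build_variant(VariantFlags(), nc=5), seed=0).eval()
        with pytest.raises(ValueError):
            with no_grad():
                model(Tensor(np.zeros((1, 3, 150, 150), np.float32)))

    def test_seeded_determinism(self):
        x = np.random.default_rng(1).random((1, 3, 96, 96), dtype=np.float32)
        outs = []
        for _ in range(2):
            model = DetectorModel(build_variant(VariantFlags(), nc=5), seed=42).eval()
            with no_grad():
                outs.append(model(Tensor(x))[0].data)
        assert np.array_equal(outs[0], outs[1])


class TestNMS:
    def _ds(self, boxes, scores, classes):
        return DetectionSet(np.array(boxes, np.float32), np.array(scores, np.float32),
                            np.array(classes, np.int64))

    def test_suppresses_same_class_overlap(self):
        d = self._ds([[0, 0, 10, 10], [1, 0, 10.5, 10]], [0.9, 0.8], [0, 0])
        out = nms_postprocess(d, 0.25, 0.45)
        assert len(out) == 1 and out.scores[0] == pytest.approx(0.9)

    def test_keeps_different_classes(self):
        d = self._ds([[0, 0, 10, 10], [1, 0, 10.5, 10]], [0.9, 0.8], [0, 1])
        assert len(nms_postprocess(d, 0.25, 0.45)) == 2

    def test_empty_input(self):
        assert len(nms_postprocess(DetectionSet.empty(), 0.25, 0.45)) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 50, (30, 2))
        wh = rng.uniform(5, 15, (30, 2))
        d = self._ds(np.hstack([xy, xy + wh]), rng.uniform(0.3, 1, 30),
                     rng.integers(0, 3, 30))
        once = nms_postprocess(d, 0.25, 0.45)
        twice = nms_postprocess(once, 0.25, 0.45)
        assert np.array_equal(once.boxes, twice.boxes)
        assert np.array_equal(once.scores, twice.scores)

    def test_scores_sorted_and_clipped(self):
        d = self._ds([[-5, -5, 10, 10], [20, 20, 40, 40]], [0.5, 0.9], [0, 1])
        out = nms_postprocess(d, 0.25, 0.45, img_wh=(32, 32))
        assert np.all(np.diff(out.scores) <= 0)
        assert out.boxes.min() >= 0 and out.boxes.max() <= 32


def test_box_iou_matrix_basics():
    a = np.array([[0, 0, 2, 2]], np.float32)
    b = np.array([[1, 1, 3, 3], [10, 10, 11, 11]], np.float32)
    m = box_iou_matrix(a, b)
    assert m[0, 0] == pytest.approx(1 / 7)
    assert m[0, 1] == 0.0
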