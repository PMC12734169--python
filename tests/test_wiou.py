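"""Wise-IoU loss family: scalar identities, gradient contracts, and the
rasterisation oracle for IoU."""
import math

import numpy as np
import pytest

from pestdet.nn import Tensor
from pestdet.wiou_losses import (Box, BoxPair, ConfigError, FocusingParams,
                                 InvalidBoxError, OutlierState, ciou_t,
                                 focusing_gamma, iou, iou_t, rwiou, wiou_v1,
                                 wiou_v1_t, wiou_v3, wiou_v3_t)

FP = FocusingParams()  # alpha=1.9, delta=3


def raster_iou(pair: BoxPair, cells: int = 20000) -> float:
    """Rasterisation oracle: count grid cells inside each half-open box over
    the joint extent.  Axis-aligned boxes factorise, so the 2-D cell counts
    are products of 1-D counts, letting the grid be very fine."""
    x_lo = min(pair.pred.x1, pair.gt.x1)
    x_hi = max(pair.pred.x2, pair.gt.x2)
    y_lo = min(pair.pred.y1, pair.gt.y1)
    y_hi = max(pair.pred.y2, pair.gt.y2)
    xs = np.linspace(x_lo, x_hi, cells, endpoint=False) + (x_hi - x_lo) / cells / 2
    ys = np.linspace(y_lo, y_hi, cells, endpoint=False) + (y_hi - y_lo) / cells / 2

    def counts(b):
        in_x = (xs >= b.x1) & (xs < b.x2)
        in_y = (ys >= b.y1) & (ys < b.y2)
        return in_x, in_y

    pax, pay = counts(pair.pred)
    gax, gay = counts(pair.gt)
    area_p = pax.sum() * pay.sum()
    area_g = gax.sum() * gay.sum()
    inter = (pax & gax).sum() * (pay & gay).sum()
    union = area_p + area_g - inter
    return float(inter / union) if union else 0.0


class TestIoU:
    def test_identical_boxes(self):
        assert iou(BoxPair(Box(1, 2, 3, 4), Box(1, 2, 3, 4))) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(BoxPair(Box(0, 0, 1, 1), Box(5, 5, 1, 1))) == 0.0

    def test_unit_overlap_example(self):
        # corners (0,0)-(2,2) and (1,1)-(3,3): intersection 1, union 7
        pair = BoxPair(Box(1, 1, 2, 2), Box(2, 2, 2, 2))
        assert iou(pair) == pytest.approx(1 / 7, abs=1e-6)
        assert raster_iou(pair) == pytest.approx(1 / 7, abs=1e-4)

    def test_invalid_dims_rejected(self):
        with pytest.raises(InvalidBoxError):
            Box(0, 0, -1, 1)

    def test_matches_rasterisation_on_random_pairs(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            p = Box(*rng.uniform(0.5, 3, 2), *rng.uniform(0.5, 2.5, 2))
            g = Box(*rng.uniform(0.5, 3, 2), *rng.uniform(0.5, 2.5, 2))
            pair = BoxPair(p, g)
            worst = max(worst, abs(iou(pair) - raster_iou(pair)))
        assert worst < 1e-3


class TestRWIoU:
    def test_coincident_centres(self):
        assert rwiou(BoxPair(Box(0, 0, 2, 1), Box(0, 0, 1, 3))) == pytest.approx(1.0)

    def test_scalar_example(self):
        # centres (0,0) and (3,4); enclosure 4 x 5 -> exp(25/41)
        pair = BoxPair(Box(0, 0, 1, 1), Box(3, 4, 1, 1))
        assert rwiou(pair) == pytest.approx(math.exp(25 / 41), rel=1e-5)

    def test_range_one_to_e(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            pair = BoxPair(Box(*rng.uniform(0, 4, 2), *rng.uniform(0.2, 2, 2)),
                           Box(*rng.uniform(0, 4, 2), *rng.uniform(0.2, 2, 2)))
            assert 1.0 <= rwiou(pair) < math.e + 1e-6


class TestWIoUv1:
    def test_identical_boxes_zero(self):
        assert wiou_v1(BoxPair(Box(0, 0, 2, 2), Box(0, 0, 2, 2))) == pytest.approx(0.0)

    def test_coincident_centres_half_iou(self):
        pair = BoxPair(Box(0, 0, 2, 1), Box(0, 0, 1, 2))  # IoU = 1/3... choose IoU=0.5
        pair = BoxPair(Box(0, 0, 2, 2), Box(0, 0, 2, 1))  # inter 2, union 4
        assert wiou_v1(pair) == pytest.approx(0.5, rel=1e-6)

    def test_factorises(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pair = BoxPair(Box(*rng.uniform(0, 3, 2), *rng.uniform(0.3, 2, 2)),
                           Box(*rng.uniform(0, 3, 2), *rng.uniform(0.3, 2, 2)))
            assert wiou_v1(pair) == pytest.approx(
                rwiou(pair) * (1 - iou(pair)), rel=1e-6)

    def test_range(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            pair = BoxPair(Box(*rng.uniform(0, 3, 2), *rng.uniform(0.3, 2, 2)),
                           Box(*rng.uniform(0, 3, 2), *rng.uniform(0.3, 2, 2)))
            assert 0.0 <= wiou_v1(pair) < math.e


class TestFocusingGamma:
    def test_unit_gain_at_delta(self):
        assert focusing_gamma(3.0, FP) == pytest.approx(1.0)

    def test_beta_one_value(self):
        assert focusing_gamma(1.0, FP) == pytest.approx((1 / 3) * 1.9 ** 2)

    def test_large_beta_suppressed(self):
        assert focusing_gamma(50.0, FP) < 1e-3

    def test_nonmonotonic_with_argmax_at_inv_log_alpha(self):
        grid = np.linspace(1e-4, 20, 200001)
        gam = grid / (FP.delta * FP.alpha ** (grid - FP.delta))
        best = grid[np.argmax(gam)]
        assert best == pytest.approx(1 / math.log(1.9), abs=1e-3)
        assert best == pytest.approx(FP.beta_argmax, abs=1e-3)
        # rises before the peak, falls after
        k = np.argmax(gam)
        assert np.all(np.diff(gam[:k]) > 0) and np.all(np.diff(gam[k + 1:]) < 0)

    def test_invalid_alpha(self):
        with pytest.raises(ConfigError):
            FocusingParams(alpha=-1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(InvalidBoxError):
            focusing_gamma(-0.5, FP)


class TestWIoUv3:
    def test_identical_boxes_zero_any_state(self):
        for mean in (0.1, 0.5, 2.0):
            st = OutlierState(mean=mean, initialized=True)
            loss, _ = wiou_v3(BoxPair(Box(0, 0, 1, 1), Box(0, 0, 1, 1)), st)
            assert loss == pytest.approx(0.0)

    def test_beta_one_coefficient(self):
        pair = BoxPair(Box(0, 0, 2, 2), Box(0.5, 0, 2, 2))
        liou = 1 - iou(pair)
        st = OutlierState(mean=liou, initialized=True)
        loss, _ = wiou_v3(pair, st)
        assert loss == pytest.approx(focusing_gamma(1.0, FP) * wiou_v1(pair), rel=1e-6)
        assert focusing_gamma(1.0, FP) == pytest.approx(1.2033333, abs=1e-6)

    def test_warm_start_uses_current_loss(self):
        pair = BoxPair(Box(0, 0, 2, 2), Box(1, 1, 2, 2))
        loss, st = wiou_v3(pair, OutlierState())
        # beta = 1 on the very first observation
        assert loss == pytest.approx(focusing_gamma(1.0, FP) * wiou_v1(pair), rel=1e-6)
        assert st.initialized

    def test_constant_stream_converges_to_fixed_point(self):
        pair = BoxPair(Box(0, 0, 2, 2), Box(0.6, 0.2, 2, 2))
        liou = 1 - iou(pair)
        st = OutlierState(momentum=0.9)
        for _ in range(300):
            _, st = wiou_v3(pair, st)
        assert st.mean == pytest.approx(liou, rel=1e-6)

    def test_dynamic_criterion_scale_invariance(self):
        """Scaling every box (hence the whole loss stream) leaves the
        long-run beta sequence unchanged: the quality split is relative."""
        rng = np.random.default_rng(5)
        offsets = rng.uniform(-0.5, 0.5, (50, 2))

        def beta_seq(scale):
            st = OutlierState(momentum=0.9)
            betas = []
            for dx, dy in offsets:
                pair = BoxPair(Box(0, 0, 2 * scale, 2 * scale),
                               Box(dx * scale, dy * scale, 2 * scale, 2 * scale))
                liou = 1 - iou(pair)
                mean = liou if not st.initialized else st.mean
                betas.append(liou / max(mean, 1e-9))
                _, st = wiou_v3(pair, st)
            return np.array(betas)

        assert np.allclose(beta_seq(1.0), beta_seq(7.0), rtol=1e-5)


class TestGradientContracts:
    def test_enclosure_detached(self):
        """Growing the enclosure (by moving the gt corners outward while
        keeping centres fixed) changes the loss value, but the gradient must
        flow only through distance and overlap terms, never the diagonal."""
        pred_np = np.array([[0.0, 0.0, 2.0, 2.0]], np.float32)
        pred = Tensor(pred_np, requires_grad=True)
        gt = Tensor(np.array([[1.0, 1.0, 2.0, 2.0]], np.float32))
        from pestdet.wiou_losses import rwiou_t

        loss = rwiou_t(pred, gt).sum()
        loss.backward()
        # analytic gradient with diag2 as a constant
        d2 = 2.0
        diag2 = 3.0 ** 2 + 3.0 ** 2
        val = math.exp(d2 / diag2)
        # d/dcx exp(((cx-1)^2+(cy-1)^2)/diag2) at cx=0 -> val * 2*(0-1)/diag2
        assert pred.grad[0, 0] == pytest.approx(val * 2 * (-1) / diag2, rel=1e-4)
        # width affects the (detached) enclosure only -> zero gradient
        assert pred.grad[0, 2] == pytest.approx(0.0, abs=1e-7)

    def test_beta_carries_no_gradient(self):
        pred = Tensor(np.array([[0.0, 0.0, 2.0, 2.0]], np.float32), requires_grad=True)
        gt = Tensor(np.array([[0.5, 0.5, 2.0, 2.0]], np.float32))
        st = OutlierState(mean=0.4, initialized=True)
        loss, _ = wiou_v3_t(pred, gt, st)
        loss.sum().backward()
        g_v3 = pred.grad.copy()
        # gamma acts as a constant multiplier on the v1 gradient
        pred2 = Tensor(pred.data, requires_grad=True)
        wiou_v1_t(pred2, gt).sum().backward()
        liou = 1 - float(iou_t(Tensor(pred.data), gt).data[0])
        gamma = focusing_gamma(liou / 0.4)
        assert np.allclose(g_v3, gamma * pred2.grad, rtol=1e-5)

    def test_ciou_matches_iou_at_same_shape(self):
        pred = Tensor(np.array([[0.0, 0.0, 2.0, 2.0]], np.float32))
        gt = Tensor(np.array([[0.0, 0.0, 2.0, 2.0]], np.float32))
        assert float(ciou_t(pred, gt).data[0]) == pytest.approx(0.0, abs=1e-6)
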