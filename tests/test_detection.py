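"""Detection head: anchor construction, target assignment, the focal and
smooth-L1 losses (limit cases frozen by hand arithmetic), box transform
inverses, and NMS against a brute-force oracle."""

import numpy as np
import pytest

from diana import nn
from diana.detection import (DetectionHeadConfig, Detection, assign_targets,
                             box_subnet, class_subnet, decode_boxes,
                             decode_detections, encode_boxes, focal_loss,
                             generate_anchors, nms, smooth_l1)
from diana.metrics import box_iou
from diana.nn import tensor as T
from oracles import nms_oracle


@pytest.fixture
def cfg():
    return DetectionHeadConfig()


class TestAnchors:
    def test_count_per_level(self, cfg):
        anchors = generate_anchors({3: (4, 4)}, {3: 8}, cfg)
        assert anchors[3].shape == (4 * 4 * cfg.n_anchors, 4)

    def test_unit_scale_square_anchor_size_matches_stride(self):
        cfg = DetectionHeadConfig(scales=(1.0,), ratios=(1.0,), anchor_scale=1.0)
        a = generate_anchors({1: (2, 2)}, {1: 8}, cfg)[1]
        np.testing.assert_allclose(a[:, 2] - a[:, 0], 8.0)
        np.testing.assert_allclose(a[:, 3] - a[:, 1], 8.0)
        # centered on cell centers
        np.testing.assert_allclose(a[0, :2], [4 - 4, 4 - 4])

    def test_anchors_finite_and_centered(self, cfg):
        a = generate_anchors({2: (8, 8)}, {2: 4}, cfg)[2]
        assert np.isfinite(a).all()
        cx = (a[:, 0] + a[:, 2]) / 2
        assert set(np.round(np.unique(cx), 6)) == {2.0, 6.0, 10.0, 14.0,
                                                   18.0, 22.0, 26.0, 30.0}


class TestBoxTransform:
    def test_encode_decode_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            xy = rng.uniform(0, 100, (10, 2))
            wh = rng.uniform(1, 30, (10, 2))
            anchors = np.concatenate([xy, xy + wh], axis=1)
            bxy = xy + rng.uniform(-5, 5, (10, 2))
            bwh = rng.uniform(0.5, 40, (10, 2))
            boxes = np.concatenate([bxy, bxy + bwh], axis=1)
            deltas = encode_boxes(anchors, boxes)
            np.testing.assert_allclose(decode_boxes(anchors, deltas), boxes,
                                       atol=1e-9)

    def test_zero_delta_is_identity(self):
        anchors = np.array([[2.0, 3.0, 10.0, 9.0]])
        np.testing.assert_allclose(decode_boxes(anchors, np.zeros((1, 4))),
                                   anchors)


class TestAssignment:
    def test_anchor_equal_to_gt_positive_with_zero_delta(self, cfg):
        anchors = np.array([[0, 0, 10, 10], [20, 20, 30, 30]], dtype=float)
        gt = np.array([[0, 0, 10, 10]], dtype=float)
        cls_t, cls_w, box_t, box_w = assign_targets(anchors, gt,
                                                    np.array([3]), cfg)
        assert box_w[0] == 1 and box_w[1] == 0
        assert cls_t[0, 2] == 1  # class 3 -> column index 2
        np.testing.assert_allclose(box_t[0], 0.0, atol=1e-12)

    def test_force_match_low_iou_gt(self, cfg):
        anchors = np.array([[0, 0, 10, 10], [50, 50, 60, 60]], dtype=float)
        gt = np.array([[30, 30, 34, 34]], dtype=float)  # overlaps nothing
        _t, _w, _bt, box_w = assign_targets(anchors, gt, np.array([1]), cfg)
        assert box_w.sum() == 1  # still one positive via force-match

    def test_empty_gt_all_negative(self, cfg):
        anchors = np.array([[0, 0, 10, 10]], dtype=float)
        cls_t, cls_w, _bt, box_w = assign_targets(
            anchors, np.zeros((0, 4)), np.zeros(0, int), cfg)
        assert cls_t.sum() == 0 and box_w.sum() == 0 and cls_w.all()


class TestFocalLoss:
    def test_gamma_zero_alpha_half_is_half_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, (40, 6))  # float64: exact comparison
        y = (rng.random((40, 6)) < 0.2).astype(np.float64)
        w = np.ones(40, dtype=np.float64)
        loss = focal_loss(nn.Tensor(p), y, w, alpha=0.5, gamma=0.0)
        n_pos = max((y.sum(axis=1) > 0).sum(), 1)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum() / n_pos
        np.testing.assert_allclose(float(loss.data), 0.5 * bce, rtol=1e-9)

    def test_perfect_prediction_loss_vanishes(self):
        y = np.eye(4, 6, dtype=np.float32)
        p = np.where(y > 0, 1.0 - 1e-7, 1e-7).astype(np.float32)
        loss = focal_loss(nn.Tensor(p), y, np.ones(4, np.float32))
        assert float(loss.data) < 1e-4

    def test_hand_value_at_p_half(self):
        # single positive element at p_t = 0.5: 0.25 * 0.5^1.8 * ln 2
        y = np.array([[1.0]], dtype=np.float32)
        p = np.array([[0.5]], dtype=np.float32)
        loss = focal_loss(nn.Tensor(p), y, np.ones(1, np.float32),
                          alpha=0.25, gamma=1.8)
        np.testing.assert_allclose(float(loss.data),
                                   0.25 * 0.5 ** 1.8 * np.log(2), rtol=1e-5)

    def test_monotone_decreasing_in_pt_for_positives(self):
        y = np.array([[1.0]], dtype=np.float32)
        vals = [float(focal_loss(nn.Tensor(np.array([[p]], np.float32)), y,
                                 np.ones(1, np.float32)).data)
                for p in np.linspace(0.05, 0.95, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ignored_anchors_contribute_nothing(self):
        y = np.zeros((2, 6), dtype=np.float32)
        p = np.full((2, 6), 0.3, dtype=np.float32)
        full = focal_loss(nn.Tensor(p), y, np.ones(2, np.float32))
        half = focal_loss(nn.Tensor(p), y, np.array([1, 0], np.float32))
        np.testing.assert_allclose(float(half.data), float(full.data) / 2,
                                   rtol=1e-6)


class TestSmoothL1:
    def test_exact_prediction_zero(self):
        t = np.random.default_rng(0).normal(size=(5, 4)).astype(np.float32)
        loss = smooth_l1(nn.Tensor(t.copy()), t, np.ones(5, np.float32))
        assert float(loss.data) == 0.0

    def test_continuity_at_branch_point(self):
        beta = 0.5
        t = np.zeros((1, 4), dtype=np.float32)
        w = np.ones(1, np.float32)
        eps = 1e-5
        below = smooth_l1(nn.Tensor(np.full((1, 4), beta - eps, np.float32)),
                          t, w, beta=beta)
        above = smooth_l1(nn.Tensor(np.full((1, 4), beta + eps, np.float32)),
                          t, w, beta=beta)
        at = smooth_l1(nn.Tensor(np.full((1, 4), beta, np.float32)), t, w,
                       beta=beta)
        np.testing.assert_allclose(float(at.data), 4 * 0.5 * beta, rtol=1e-5)
        assert abs(float(above.data) - float(below.data)) < 1e-3

    def test_linear_branch_value(self):
        # d = 2, beta = 1 -> 1.5 per element
        pred = nn.Tensor(np.array([[2.0, 0, 0, 0]], np.float32))
        loss = smooth_l1(pred, np.zeros((1, 4), np.float32),
                         np.ones(1, np.float32), beta=1.0)
        np.testing.assert_allclose(float(loss.data), 1.5, rtol=1e-6)

    def test_no_positives_returns_zero(self):
        loss = smooth_l1(nn.Tensor(np.ones((3, 4), np.float32)),
                         np.zeros((3, 4), np.float32), np.zeros(3, np.float32))
        assert float(loss.data) == 0.0


class TestNMS:
    def test_matches_bruteforce_on_random_boxes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            xy = rng.uniform(0, 50, (n, 2))
            wh = rng.uniform(2, 20, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.random(n)
            assert nms(boxes, scores, 0.5) == nms_oracle(boxes, scores, 0.5)

    def test_decode_identical_boxes_same_class_one_survivor(self, cfg):
        anchors = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        probs = np.zeros((2, 6))
        probs[:, 0] = [0.9, 0.8]
        dets = decode_detections(probs, np.zeros((2, 4)), anchors, cfg, (20, 20))
        assert len(dets) == 1 and dets[0].score == 0.9

    def test_decode_identical_boxes_different_classes_both_survive(self, cfg):
        anchors = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        probs = np.zeros((2, 6))
        probs[0, 0] = 0.9
        probs[1, 3] = 0.8
        dets = decode_detections(probs, np.zeros((2, 4)), anchors, cfg, (20, 20))
        assert len(dets) == 2

    def test_decode_all_below_threshold_empty(self, cfg):
        anchors = np.array([[0, 0, 10, 10]], dtype=float)
        probs = np.full((1, 6), 0.1)
        assert decode_detections(probs, np.zeros((1, 4)), anchors, cfg,
                                 (20, 20)) == []


class TestSubnets:
    def test_hidden_depth_matches_config(self, cfg):
        net = class_subnet(cfg, 8, rng=np.random.default_rng(0))
        assert len(net.hidden) == cfg.m_class == 4

    def test_box_subnet_output_channels(self, cfg):
        net = box_subnet(cfg, 8, rng=np.random.default_rng(0))
        assert net.pred.weight.shape[0] == cfg.n_anchors * 4

    def test_prior_probability_initialization(self, cfg):
        net = class_subnet(cfg, 8, rng=np.random.default_rng(1)).eval()
        x = nn.Tensor(np.random.default_rng(2)
                      .normal(size=(1, 8, 4, 4)).astype(np.float32))
        probs = 1 / (1 + np.exp(-net(x).data))
        np.testing.assert_allclose(probs, cfg.prior_prob, rtol=0.5)

    def test_weight_sharing_across_levels(self, cfg):
        net = class_subnet(cfg, 8, rng=np.random.default_rng(3)).eval()
        x = np.random.default_rng(4).normal(size=(1, 8, 4, 4)).astype(np.float32)
        out1 = net(nn.Tensor(x)).data
        out2 = net(nn.Tensor(x)).data  # same weights applied at another "level"
        np.testing.assert_array_equal(out1, out2)
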