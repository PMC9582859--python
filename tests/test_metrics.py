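"""Metric implementations against independent brute-force oracles, plus the
frozen hand-computed cases and the structural invariants (PQ = DQ x SQ,
symmetry, false-positive monotonicity)."""

import numpy as np
import pytest

from diana.metrics import (average_precision, box_iou, detection_confusion,
                           iou, miou, panoptic_quality, pr_curve,
                           segmentation_confusion, size_stratified_ap)
from oracles import ap_oracle, pq_oracle, random_instances


def rasterized_iou(box_a, box_b, grid=200):
    """Pixel-counting IoU for integer boxes: an oracle independent of the
    interval arithmetic in box_iou."""
    a = np.zeros((grid, grid), bool)
    b = np.zeros((grid, grid), bool)
    a[int(box_a[1]):int(box_a[3]), int(box_a[0]):int(box_a[2])] = True
    b[int(box_b[1]):int(box_b[3]), int(box_b[0]):int(box_b[2])] = True
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0


# -- IoU ----------------------------------------------------------------------

class TestIoU:
    def test_identity_and_disjoint(self):
        box = np.array([2, 3, 10, 12], float)
        assert iou(box, box) == 1.0
        assert iou(box, np.array([20, 20, 30, 30], float)) == 0.0

    def test_hand_case_two_sixths(self):
        # [0,0,2,2] and [1,0,3,2]: intersection 2, union 6
        assert iou(np.array([0, 0, 2, 2]), np.array([1, 0, 3, 2])) == pytest.approx(2 / 6)

    def test_symmetry_against_rasterized_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = np.sort(rng.integers(0, 100, 4).reshape(2, 2), axis=0).T.ravel()
            b = np.sort(rng.integers(0, 100, 4).reshape(2, 2), axis=0).T.ravel()
            a = np.array([a[0], a[2], a[1] + 1, a[3] + 1])
            b = np.array([b[0], b[2], b[1] + 1, b[3] + 1])
            v = iou(a, b)
            assert v == pytest.approx(iou(b, a))
            assert v == pytest.approx(rasterized_iou(a, b, 200))

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_pixel_set_iou(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4] = True
        b[2:6] = True
        assert iou(a, b) == pytest.approx(16 / 48)


# -- AP -----------------------------------------------------------------------

class TestAveragePrecision:
    def test_perfect_detections(self):
        gts = [(1, 1, np.array([0, 0, 10, 10])), (1, 2, np.array([20, 20, 30, 30]))]
        dets = [(1, 1, np.array([0, 0, 10, 10]), 0.9),
                (1, 2, np.array([20, 20, 30, 30]), 0.8)]
        res = average_precision(dets, gts)
        assert res["mAP"] == 1.0

    def test_single_miss_is_zero(self):
        gts = [(1, 1, np.array([0, 0, 10, 10]))]
        dets = [(1, 1, np.array([50, 50, 60, 60]), 0.9)]
        assert average_precision(dets, gts)["mAP"] == 0.0

    def test_frozen_tp_fp_tp_case(self):
        # 2 gts; detections scored .9 (TP), .8 (FP), .7 (TP):
        # AP = 0.5*1 + 0.5*(2/3)
        gts = [(1, 1, np.array([0, 0, 10, 10])),
               (1, 1, np.array([30, 30, 40, 40]))]
        dets = [(1, 1, np.array([0, 0, 10, 10]), 0.9),
                (1, 1, np.array([60, 60, 70, 70]), 0.8),
                (1, 1, np.array([30, 30, 40, 40]), 0.7)]
        res = average_precision(dets, gts)
        assert res["mAP"] == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_matches_bruteforce_oracle_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_img = int(rng.integers(1, 3))
            gts, dets = [], []
            for img in range(n_img):
                for _ in range(int(rng.integers(0, 6))):
                    xy = rng.integers(0, 40, 2)
                    wh = rng.integers(4, 20, 2)
                    gts.append((img, 1, np.array([*xy, *(xy + wh)], float)))
                for _ in range(int(rng.integers(0, 8))):
                    xy = rng.integers(0, 40, 2)
                    wh = rng.integers(4, 20, 2)
                    dets.append((img, 1, np.array([*xy, *(xy + wh)], float),
                                 float(rng.random())))
            if not gts:
                continue
            mine = average_precision(dets, gts)["per_class"].get(1, np.nan)
            ref = ap_oracle(dets, gts, 0.5)
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_adding_false_positive_never_increases_ap(self):
        rng = np.random.default_rng(8)
        gts = [(1, 1, np.array([0, 0, 10, 10], float)),
               (1, 1, np.array([30, 0, 42, 10], float))]
        dets = [(1, 1, np.array([0, 0, 10, 10], float), 0.6)]
        base = average_precision(dets, gts)["mAP"]
        for _ in range(20):
            fp = (1, 1, np.array([60, 60, 70, 70], float), float(rng.random()))
            worse = average_precision(dets + [fp], gts)["mAP"]
            assert worse <= base + 1e-12

    def test_coco_style_averages_thresholds(self):
        gts = [(1, 1, np.array([0, 0, 10, 10], float))]
        # prediction inside the gt with area 72: IoU 0.72, so it counts as a
        # hit at thresholds 0.50..0.70 (5 of the 10 COCO thresholds)
        dets = [(1, 1, np.array([0, 0, 9, 8], float), 0.9)]
        res = average_precision(dets, gts, coco_style=True)
        assert res["mAP"] == pytest.approx(5 / 10)


class TestSizeStratifiedAP:
    def test_bins_and_boundaries(self):
        gts = [(1, 1, np.array([0, 0, 10, 10], float)),        # area 100: small
               (1, 1, np.array([0, 0, 32, 32], float)),        # 32^2: medium
               (1, 1, np.array([0, 0, 100, 100], float))]      # large
        dets = [(1, 1, g[2], 0.9) for g in gts]
        res = size_stratified_ap(dets, gts)
        assert set(res) == {"small", "medium", "large"}

    def test_empty_bin_absent(self):
        gts = [(1, 1, np.array([0, 0, 10, 10], float))]
        res = size_stratified_ap([(1, 1, gts[0][2], 0.9)], gts)
        assert set(res) == {"small"}
        assert res["small"] == 1.0


# -- PQ -----------------------------------------------------------------------

class TestPanopticQuality:
    def test_identity(self):
        rng = np.random.default_rng(1)
        inst = random_instances(rng)
        if not inst:
            inst = [(1, np.pad(np.ones((4, 4), bool), ((0, 60), (0, 60))))]
        res = panoptic_quality(inst, inst)
        assert res.mPQ == pytest.approx(1.0)
        assert res.mDQ == pytest.approx(1.0) and res.mSQ == pytest.approx(1.0)

    def test_frozen_tp_fp_fn_case(self):
        # 1 TP at IoU 0.75 + 1 FP + 1 FN: DQ = 0.5, SQ = 0.75, PQ = 0.375
        g1 = np.zeros((32, 32), bool)
        g1[0:8, 0:8] = True
        p1 = np.zeros((32, 32), bool)
        p1[0:8, 0:6] = True  # IoU 6/8 = 0.75
        fp = np.zeros((32, 32), bool)
        fp[20:24, 20:24] = True
        g2 = np.zeros((32, 32), bool)
        g2[28:32, 28:32] = True
        res = panoptic_quality([(1, p1), (1, fp)], [(1, g1), (1, g2)])
        c = res.per_class[1]
        assert c["DQ"] == pytest.approx(0.5)
        assert c["SQ"] == pytest.approx(0.75)
        assert c["PQ"] == pytest.approx(0.375)

    def test_matches_exhaustive_oracle_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pred = random_instances(rng)
            gt = random_instances(rng)
            res = panoptic_quality(pred, gt)
            ref = pq_oracle(pred, gt)
            for c, pq_ref in ref.items():
                assert res.per_class[c]["PQ"] == pytest.approx(pq_ref, abs=1e-12)

    def test_pq_equals_dq_times_sq_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            res = panoptic_quality(random_instances(rng), random_instances(rng))
            for v in res.per_class.values():
                assert abs(v["PQ"] - v["DQ"] * v["SQ"]) < 1e-12

    def test_sq_zero_flagged_when_no_tp(self):
        m = np.zeros((8, 8), bool)
        m[:2, :2] = True
        res = panoptic_quality([(1, m)], [])
        assert res.per_class[1]["SQ"] == 0.0
        assert not res.per_class[1]["SQ_defined"]

    def test_overlapping_instances_rejected(self):
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="overlapping"):
            panoptic_quality([(1, m), (2, m)], [])

    def test_adding_false_positive_never_increases_pq(self):
        rng = np.random.default_rng(4)
        gt = random_instances(rng, n_max=5)
        pred = [(c, m.copy()) for c, m in gt]
        base = panoptic_quality(pred, gt).mPQ
        fp = np.zeros((64, 64), bool)
        fp[60:64, 60:64] = True
        fp &= ~np.logical_or.reduce([m for _c, m in pred]) if pred else fp
        if fp.sum():
            worse = panoptic_quality(pred + [(1, fp)], gt).mPQ
            assert worse <= base + 1e-12


# -- mIOU & confusion ----------------------------------------------------------

class TestMiou:
    def test_identical_masks(self):
        m = np.random.default_rng(0).integers(0, 4, (16, 16))
        assert miou(m, m)["mIOU"] == 1.0

    def test_complementary_binary_masks(self):
        a = np.zeros((8, 8), int)
        a[:4] = 1
        b = 1 - a
        assert miou(a, b)["mIOU"] == 0.0

    def test_half_overlap_stripes(self):
        # class stripes shifted by half a period: IoU = 1/3 per class
        gt = np.zeros((8, 8), int)
        gt[:, :4] = 1
        gt[:, 4:] = 2
        pred = np.zeros((8, 8), int)
        pred[:, 2:6] = 1
        pred[:, 6:] = 2
        pred[:, :2] = 2
        res = miou(pred, gt)
        assert res["per_class"][1] == pytest.approx(1 / 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            miou(np.zeros((4, 4)), np.zeros((5, 5)))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        gts = [(1, c, np.array([c * 20, 0, c * 20 + 10, 10], float))
               for c in (1, 2, 3)]
        dets = [(1, c, g[2], 0.9) for (_, c, g2), g in zip(gts, gts) for _ in [0]]
        cm = detection_confusion([(1, c, b, 0.9) for _, c, b in gts], gts, 3)
        assert (np.diag(cm)[1:] == 1).all()
        assert cm.sum() == 3

    def test_all_background_prediction_mass_in_background(self):
        gts = [(1, 1, np.array([0, 0, 10, 10], float))]
        cm = detection_confusion([], gts, 2)
        assert cm[1, 0] == 1 and cm.sum() == 1

    def test_pixel_confusion_row_sums_conserve_gt(self):
        rng = np.random.default_rng(5)
        gt = rng.integers(0, 4, (32, 32))
        pred = rng.integers(0, 4, (32, 32))
        cm = segmentation_confusion(pred, gt, 3)
        for c in range(4):
            assert cm[c].sum() == (gt == c).sum()


class TestPRCurve:
    def test_monotone_recall_and_final_point(self):
        gts = [(1, 1, np.array([0, 0, 10, 10], float)),
               (1, 1, np.array([30, 30, 40, 40], float))]
        dets = [(1, 1, np.array([0, 0, 10, 10], float), 0.9),
                (1, 1, np.array([60, 60, 70, 70], float), 0.8),
                (1, 1, np.array([30, 30, 40, 40], float), 0.7)]
        pr = pr_curve(dets, gts, class_id=1)
        assert (np.diff(pr["recall"]) >= 0).all()
        assert pr["recall"][-1] == 1.0
        assert pr["precision"][0] == 1.0
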