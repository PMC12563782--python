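"""Metric kernels against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats

from finseg.annotations import BoundingBox
from finseg.metrics import (
    MatchCounts,
    average_precision,
    box_iou,
    detection_map,
    match_detections,
    mean_average_precision,
    mean_iou,
    paired_t_test,
    pixel_accuracy,
    segmentation_class_precision,
    throughput,
)


def _random_boxes(rng, n, size=100, cls_max=2):
    boxes = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, size - 10, 2)
        w, h = rng.uniform(2, 30, 2)
        boxes.append(BoundingBox(int(rng.integers(0, cls_max)), x0, y0,
                                 min(x0 + w, size), min(y0 + h, size),
                                 float(rng.random())))
    return boxes


class TestMatching:
    def test_perfect_predictions(self, rng):
        gt = _random_boxes(rng, 5)
        preds = [BoundingBox(b.class_id, b.x_min, b.y_min, b.x_max, b.y_max, 0.9)
                 for b in gt]
        counts, _ = match_detections([preds], [gt], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (5, 0, 0)
        assert counts.precision == 1.0 and counts.recall == 1.0

    def test_no_predictions_flagged_zero(self, rng):
        gt = _random_boxes(rng, 3)
        counts, flags = match_detections([[]], [gt], 0.5)
        assert (counts.tp, counts.fn) == (0, 3)
        assert counts.precision == 0.0 and counts.recall == 0.0
        assert flags == []

    def test_hand_constructed_counts(self):
        gt = [BoundingBox(0, 0, 0, 10, 10), BoundingBox(0, 20, 20, 30, 30)]
        preds = [
            BoundingBox(0, 0, 0, 10, 10, 0.9),       # hit
            BoundingBox(0, 21, 21, 31, 31, 0.8),     # hit (IoU ~0.68)
            BoundingBox(0, 50, 50, 60, 60, 0.7),     # miss
        ]
        counts, _ = match_detections([preds], [gt], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 0)

    def test_one_match_per_ground_truth(self):
        gt = [BoundingBox(0, 0, 0, 10, 10)]
        preds = [BoundingBox(0, 0, 0, 10, 10, 0.9),
                 BoundingBox(0, 1, 1, 11, 11, 0.8)]
        counts, flags = match_detections([preds], [gt], 0.5)
        assert (counts.tp, counts.fp) == (1, 1)
        assert [f[1] for f in flags] == [True, False]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchCounts(tp=-1)


class TestAveragePrecision:
    def test_all_correct(self):
        assert average_precision([True, True, True], 3) == 1.0

    def test_hand_computed_envelope(self):
        # flags (TP, FP, TP), 2 ground truths:
        # recall 0.5 @ P=1, recall 1.0 @ P=2/3 -> AP = 0.5*1 + 0.5*(2/3)
        ap = average_precision([True, False, True], 2)
        assert ap == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_no_gt_with_predictions_zero(self):
        assert average_precision([False, False], 0) == 0.0

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        """All-point AP equals direct trapezoid-free integration of the
        step-wise precision envelope computed by exhaustive enumeration."""
        for _ in range(100):
            n = int(rng.integers(1, 30))
            n_gt = int(rng.integers(1, 20))
            flags = rng.random(n) < 0.5
            if flags.sum() > n_gt:
                flags[np.nonzero(flags)[0][n_gt:]] = False
            ap = average_precision(list(flags), n_gt)
            # oracle: walk ranks, record (recall, precision), integrate the
            # running max of precision from the right over recall steps
            pts = []
            tp = fp = 0
            for f in flags:
                tp, fp = tp + bool(f), fp + (not f)
                pts.append((tp / n_gt, tp / (tp + fp)))
            area = 0.0
            prev_r = 0.0
            for i, (r, _) in enumerate(pts):
                if r > prev_r:
                    env = max(p for rr, p in pts[i:])
                    area += (r - prev_r) * env
                    prev_r = r
            assert ap == pytest.approx(area, abs=1e-9)

    def test_invariant_to_monotone_confidence_rescale(self, rng):
        gt = [_random_boxes(rng, 6) for _ in range(3)]
        preds = [_random_boxes(rng, 8) for _ in range(3)]
        m1, _ = detection_map(preds, gt, 0.3)
        rescaled = [[BoundingBox(b.class_id, b.x_min, b.y_min, b.x_max, b.y_max,
                                 b.confidence ** 3) for b in boxes]
                    for boxes in preds]
        m2, _ = detection_map(rescaled, gt, 0.3)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_map_arithmetic(self):
        assert mean_average_precision({0: 1.0, 1: 0.5}) == 0.75
        assert mean_average_precision({0: 0.42}) == 0.42
        assert mean_average_precision({1: 0.5, 0: 1.0}) == 0.75
        with pytest.raises(ValueError):
            mean_average_precision({})


class TestSegmentationMetrics:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 4, (32, 32)).astype(np.uint8)
        per, miou = mean_iou(m, m, 3)
        assert miou == 1.0
        assert pixel_accuracy(m, m) == 1.0

    def test_half_overlapping_squares(self):
        gt = np.zeros((40, 40), np.uint8)
        pred = np.zeros((40, 40), np.uint8)
        gt[10:20, 10:20] = 1
        pred[10:20, 15:25] = 1
        per, _ = mean_iou(pred, gt, 1)
        assert per[1] == pytest.approx(50 / 150)

    def test_matches_set_operation_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 4))
            pred = rng.integers(0, k + 1, (12, 12)).astype(np.uint8)
            gt = rng.integers(0, k + 1, (12, 12)).astype(np.uint8)
            per, miou = mean_iou(pred, gt, k)
            vals = []
            for c in range(k + 1):
                p, g = pred == c, gt == c
                union = (p | g).sum()
                if union == 0:
                    assert np.isnan(per[c])
                    continue
                iou = (p & g).sum() / union
                assert per[c] == pytest.approx(iou, abs=1e-9)
                vals.append(iou)
            assert miou == pytest.approx(np.mean(vals), abs=1e-9)
            assert pixel_accuracy(pred, gt) == pytest.approx((pred == gt).mean())

    def test_orientation_symmetry(self, rng):
        pred = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        gt = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        _, a = mean_iou(pred, gt, 2)
        _, b = mean_iou(pred[::-1, ::-1], gt[::-1, ::-1], 2)
        assert a == b
        assert pixel_accuracy(pred, gt) == pixel_accuracy(pred[::-1], gt[::-1])

    def test_complement_binary_masks(self):
        a = np.zeros((8, 8), np.uint8)
        a[:4] = 1
        assert pixel_accuracy(a, 1 - a) == 0.0

    def test_hand_counted_pixel_accuracy(self):
        gt = np.zeros((4, 4), np.uint8)
        pred = gt.copy()
        pred[0, :] = 1  # 4 wrong pixels of 16
        assert pixel_accuracy(pred, gt) == 0.75

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mean_iou(np.zeros((4, 4)), np.zeros((5, 5)), 1)

    def test_class_precision_average(self):
        gt = np.zeros((10, 10), np.uint8)
        gt[:5] = 1
        pred = np.zeros((10, 10), np.uint8)
        pred[:4] = 1   # 40 predicted class-1 pixels, all correct
        m, per = segmentation_class_precision(pred, gt, 1)
        assert per[1] == 1.0 and m == 1.0


class TestThroughput:
    def test_values(self):
        assert throughput(10, 2.0) == 5.0
        assert throughput(0, 1.0) == 0.0
        with pytest.raises(ValueError):
            throughput(5, 0.0)


class TestPairedT:
    def test_identical_lists_degenerate(self):
        res = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.degenerate and res.statistic == 0.0

    def test_hand_formula(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([1.2, 0.8, 1.1, 0.9, 1.0])
        res = paired_t_test(a, b)
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.statistic == pytest.approx(expected)
        assert res.df == 4

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            a = rng.standard_normal(n)
            b = a + rng.standard_normal(n) * 0.5 + 0.1
            res = paired_t_test(a, b)
            ref = stats.ttest_rel(a, b)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert res.df == n - 1
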