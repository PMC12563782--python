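"""Detector components: Focus, grids, decoding, NMS, Mosaic, targets."""

import numpy as np
import pytest

from finseg.annotations import BoundingBox
from finseg.metrics import box_iou
from finseg.nn.tensor import Tensor
from finseg.p2_yolo import (
    DetectorConfig,
    DetTrainConfig,
    build_detector,
    decode_predictions,
    detection_loss,
    focus_slice,
    kmeans_anchors,
    load_detector,
    mosaic_augment,
    nms,
    save_detector,
    unfocus_slice,
)

TINY = dict(width_multiple=0.0625)   # 4-channel stem keeps forwards cheap


class TestFocus:
    def test_shapes(self, rng):
        x = rng.random((2, 3, 640, 640)).astype(np.float32)
        assert focus_slice(x).shape == (2, 12, 320, 320)

    def test_constant_preserved(self):
        x = np.full((1, 3, 8, 8), 3.25, np.float32)
        assert (focus_slice(x) == 3.25).all()

    def test_bijection_round_trip(self, rng):
        x = rng.random((2, 3, 16, 16)).astype(np.float32)
        assert np.array_equal(unfocus_slice(focus_slice(x)), x)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            focus_slice(np.zeros((1, 3, 7, 8), np.float32))

    def test_tensor_path_matches_numpy(self, rng):
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        assert np.array_equal(focus_slice(Tensor(x)).data, focus_slice(x))


class TestForward:
    def test_grid_sizes_at_640(self):
        model = build_detector(DetectorConfig(input_size=640, **TINY), seed=0)
        out = model(Tensor(np.zeros((1, 3, 640, 640), np.float32)))
        assert [o.shape[-1] for o in out] == [160, 80, 40, 20]

    def test_grid_sizes_at_320(self):
        model = build_detector(DetectorConfig(input_size=320, **TINY), seed=0)
        out = model(Tensor(np.zeros((1, 3, 320, 320), np.float32)))
        assert [o.shape[-1] for o in out] == [80, 40, 20, 10]

    def test_p2_disabled_drops_finest_level(self):
        model = build_detector(
            DetectorConfig(input_size=320, use_p2=False, **TINY), seed=0)
        out = model(Tensor(np.zeros((1, 3, 320, 320), np.float32)))
        assert [o.shape[-1] for o in out] == [40, 20, 10]

    def test_finite_outputs_and_wrong_size_rejected(self, rng):
        model = build_detector(DetectorConfig(input_size=160, **TINY), seed=0)
        out = model(Tensor(rng.random((2, 3, 160, 160)).astype(np.float32)))
        assert all(np.isfinite(o.data).all() for o in out)
        with pytest.raises(ValueError, match="160"):
            model(Tensor(np.zeros((1, 3, 128, 128), np.float32)))


class TestDecode:
    @pytest.fixture()
    def cfg160(self):
        return DetectorConfig(input_size=160, **TINY)

    def _zero_raw(self, cfg):
        no = 3 * (5 + cfg.n_classes)
        return [np.zeros((1, no, cfg.input_size // s, cfg.input_size // s),
                         np.float32) for s in cfg.active_strides]

    def test_zero_logits_below_default_threshold(self, cfg160):
        # sigmoid(0)^2 = 0.25 is not strictly above the 0.25 default
        boxes = decode_predictions(self._zero_raw(cfg160), cfg160)
        assert sum(len(b) for b in boxes) == 0

    def test_threshold_zero_retains_every_anchor_cell(self, cfg160):
        boxes = decode_predictions(self._zero_raw(cfg160), cfg160,
                                   conf_threshold=0.0, max_det=0)
        expected = sum(3 * (160 // s) ** 2 for s in cfg160.active_strides)
        assert len(boxes[0]) == expected

    def test_single_hot_cell_localized(self, cfg160):
        # zero logits everywhere score sigmoid(0)^2 = 0.25 < threshold;
        # one cell gets big obj+class logits for anchor 0 at (gy=3, gx=5)
        raw = self._zero_raw(cfg160)
        raw[0][0, 4, 3, 5] = 10.0
        raw[0][0, 5, 3, 5] = 10.0
        boxes = decode_predictions(raw, cfg160, conf_threshold=0.5)[0]
        assert len(boxes) == 1
        b = boxes[0]
        stride = cfg160.active_strides[0]
        cx = (b.x_min + b.x_max) / 2
        cy = (b.y_min + b.y_max) / 2
        assert abs(cx - 5.5 * stride) <= stride / 2
        assert abs(cy - 3.5 * stride) <= stride / 2
        assert b.class_id == 0

    def test_decode_recovers_encoded_targets(self, cfg160, rng):
        """Inverse check: place ground-truth boxes, write the logits the
        encoding rule dictates, decode, and require centre error below
        stride/2 and size error below 1%."""
        anchors = cfg160.level_anchors()
        raw = self._zero_raw(cfg160)
        nc = cfg160.n_classes
        base = 1 * (5 + nc)    # anchor slot 1: sizes up to 4x its anchor fit
        aw, ah = anchors[0, 1]
        gts = []
        stride = cfg160.active_strides[0]
        cells = rng.choice(30, size=(5, 2), replace=False) + 4
        for k in range(5):
            ci, cj = map(int, cells[k])
            gx = ci + rng.uniform(0.05, 0.95)
            gy = cj + rng.uniform(0.05, 0.95)
            w = float(rng.uniform(0.3 * aw, 3.5 * aw))
            h = float(rng.uniform(0.3 * ah, 3.5 * ah))
            def inv_sig(p):
                return float(np.log(p / (1 - p)))
            raw[0][0, base + 0, cj, ci] = inv_sig((gx - ci + 0.5) / 2)
            raw[0][0, base + 1, cj, ci] = inv_sig((gy - cj + 0.5) / 2)
            raw[0][0, base + 2, cj, ci] = inv_sig(np.sqrt(w / aw) / 2)
            raw[0][0, base + 3, cj, ci] = inv_sig(np.sqrt(h / ah) / 2)
            raw[0][0, base + 4, cj, ci] = 10.0
            raw[0][0, base + 5, cj, ci] = 10.0
            gts.append((gx * stride, gy * stride, w, h))
        boxes = decode_predictions(raw, cfg160, conf_threshold=0.5)[0]
        assert len(boxes) == len(gts)
        boxes = sorted(boxes, key=lambda b: (b.x_min, b.y_min))
        gts = sorted(gts)
        for b, (gx, gy, w, h) in zip(boxes, gts):
            assert abs((b.x_min + b.x_max) / 2 - gx) <= stride / 2
            assert abs((b.y_min + b.y_max) / 2 - gy) <= stride / 2
            assert abs(b.width - w) / w <= 0.01
            assert abs(b.height - h) / h <= 0.01


class TestNMS:
    def test_duplicate_suppressed(self):
        a = BoundingBox(0, 0, 0, 10, 10, 0.9)
        b = BoundingBox(0, 0, 0, 10, 10, 0.8)
        assert nms([a, b], 0.45) == [a]

    def test_disjoint_survive_and_classwise(self):
        a = BoundingBox(0, 0, 0, 10, 10, 0.9)
        b = BoundingBox(0, 50, 50, 60, 60, 0.2)
        c = BoundingBox(1, 0, 0, 10, 10, 0.5)   # other class, same place
        assert set(id(x) for x in nms([a, b, c], 0.45)) == {id(a), id(b), id(c)}

    def test_matches_bruteforce_oracle(self, rng):
        def brute(boxes, thr):
            alive = list(range(len(boxes)))
            order = sorted(alive, key=lambda i: (-boxes[i].confidence, i))
            kept = []
            for i in order:
                if all(boxes[k].class_id != boxes[i].class_id
                       or box_iou(boxes[i], boxes[k]) < thr for k in kept):
                    kept.append(i)
            return sorted(kept)

        for trial in range(100):
            trial_rng = np.random.default_rng(trial)
            boxes = []
            for _ in range(50):
                x0, y0 = trial_rng.uniform(0, 80, 2)
                w, h = trial_rng.uniform(3, 25, 2)
                boxes.append(BoundingBox(int(trial_rng.integers(0, 2)),
                                         x0, y0, x0 + w, y0 + h,
                                         float(trial_rng.random())))
            got = nms(boxes, 0.45)
            want = [boxes[i] for i in brute(boxes, 0.45)]
            assert [id(b) for b in got] == [id(b) for b in want]


class TestMosaic:
    def _sample(self, rng, size=64, n_boxes=2):
        img = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
        boxes = []
        for _ in range(n_boxes):
            x0, y0 = rng.uniform(0, size - 12, 2)
            w, h = rng.uniform(4, 10, 2)
            boxes.append(BoundingBox(int(rng.integers(0, 2)), x0, y0,
                                     x0 + w, y0 + h))
        return img, boxes

    def test_constant_images_give_constant_canvas(self):
        img = np.full((32, 32, 3), 77, np.uint8)
        canvas, _ = mosaic_augment([(img, [])] * 4, 64, seed=0)
        assert (canvas == 77).all()

    def test_box_affine_placement(self):
        img = np.zeros((64, 64, 3), np.uint8)
        box = BoundingBox(0, 8, 8, 24, 24)
        canvas, boxes = mosaic_augment([(img, [box])] + [(img, [])] * 3,
                                       128, seed=5)
        rng = np.random.default_rng(5)
        cx = int(rng.uniform(0.25, 0.75) * 128)
        cy = int(rng.uniform(0.25, 0.75) * 128)
        sx, sy = cx / 64, cy / 64
        (b,) = boxes
        assert b.x_min == pytest.approx(8 * sx)
        assert b.y_min == pytest.approx(8 * sy)
        assert b.x_max == pytest.approx(24 * sx)
        assert b.y_max == pytest.approx(24 * sy)

    def test_boxes_clipped_to_canvas(self, rng):
        for seed in range(20):
            samples = [self._sample(np.random.default_rng(seed * 4 + i))
                       for i in range(4)]
            canvas, boxes = mosaic_augment(samples, 96, seed=seed)
            assert canvas.shape == (96, 96, 3)
            for b in boxes:
                assert 0 <= b.x_min < b.x_max <= 96
                assert 0 <= b.y_min < b.y_max <= 96

    def test_wrong_sample_count(self):
        with pytest.raises(ValueError):
            mosaic_augment([(np.zeros((8, 8, 3), np.uint8), [])] * 3, 32, 0)


class TestTargetsAndLoss:
    def test_loss_finite_and_components_positive(self, rng):
        cfg = DetectorConfig(input_size=64, **TINY)
        model = build_detector(cfg, seed=0)
        raw = model(Tensor(rng.random((2, 3, 64, 64)).astype(np.float32)))
        boxes = [[BoundingBox(0, 10, 10, 18, 18), BoundingBox(1, 30, 40, 37, 46)],
                 []]
        anchors = cfg.level_anchors()
        loss, comp = detection_loss(raw, boxes, cfg, anchors, DetTrainConfig())
        assert np.isfinite(float(loss.data))
        assert comp["box"] > 0 and comp["obj"] > 0 and comp["cls"] > 0

    def test_kmeans_anchors_sorted_by_area(self, rng):
        boxes = [BoundingBox(0, 0, 0, w, h)
                 for w, h in rng.uniform(3, 60, (100, 2))]
        anchors = kmeans_anchors(boxes, 4, seed=0)
        assert anchors.shape == (4, 3, 2)
        areas = anchors.reshape(-1, 2).prod(axis=1)
        assert (np.diff(areas) >= -1e-9).all()


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = DetectorConfig(input_size=160, **TINY)
    model = build_detector(cfg, seed=4)
    model.anchors = cfg.level_anchors()
    path = tmp_path / "det.npz"
    save_detector(model, path)
    clone = load_detector(path)
    x = Tensor(rng.random((1, 3, 160, 160)).astype(np.float32))
    model.eval()
    clone.eval()
    for a, b in zip(model(x), clone(x)):
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)
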