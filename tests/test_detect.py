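import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvscreen import (BlobDetector, BoundingBox, SynthParams, blob_detect,
                      detect_exam, ensemble_detections, generate_exam, iou,
                      max_objectness, nms, read_yolo_predictions)


def _box(x0, y0, x1, y1, score=1.0, cls="suspicious_mass", src=""):
    return BoundingBox(x_min=x0, y_min=y0, x_max=x1, y_max=y1,
                       class_name=cls, objectness=score, source_model=src)


def _random_boxes(rng, n, cls_pool=("suspicious_mass", "lymph_node")):
    boxes = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, 80, 2)
        boxes.append(_box(x0, y0, x0 + rng.uniform(2, 30), y0 + rng.uniform(2, 30),
                          score=round(float(rng.uniform(0, 1)), 3),
                          cls=cls_pool[int(rng.integers(len(cls_pool)))]))
    return boxes


def _nms_oracle(boxes, thr):
    """Brute-force suppression: a box survives iff no kept higher-priority
    same-class box overlaps it at IoU >= thr; priorities checked over every pair."""
    order = sorted(range(len(boxes)),
                   key=lambda i: (-boxes[i].objectness, boxes[i].x_min, boxes[i].y_min,
                                  boxes[i].x_max, boxes[i].y_max))
    kept = []
    for i in order:
        if all(boxes[j].class_name != boxes[i].class_name or iou(boxes[j], boxes[i]) < thr
               for j in kept):
            kept.append(i)
    return {boxes[i].as_tuple() + (boxes[i].class_name,) for i in kept}


class TestIoU:
    def test_identical_is_one(self):
        b = _box(0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_is_zero(self):
        assert iou(_box(0, 0, 5, 5), _box(6, 6, 9, 9)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou(_box(0, 0, 2, 2), _box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_boxes(rng, 2)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestNMS:
    def test_empty_input(self):
        assert nms([], 0.5) == []

    def test_single_suppression_step(self):
        hi = _box(0, 0, 10, 10, score=0.9)
        lo = _box(1, 0, 11, 10, score=0.7)  # IoU 9/11 > 0.5
        assert nms([hi, lo], 0.5) == [hi]

    def test_cross_class_suppression_disabled(self):
        mass = _box(0, 0, 10, 10, score=0.9, cls="suspicious_mass")
        node = _box(0, 0, 10, 10, score=0.7, cls="lymph_node")
        assert set(b.class_name for b in nms([mass, node], 0.5)) == {
            "suspicious_mass", "lymph_node"}

    def test_matches_brute_force_oracle_on_random_sets(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            boxes = _random_boxes(rng, int(rng.integers(0, 21)))
            thr = float(rng.uniform(0.2, 0.8))
            got = {b.as_tuple() + (b.class_name,) for b in nms(boxes, thr)}
            assert got == _nms_oracle(boxes, thr)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_survivors_subset_and_antichain(self, seed):
        rng = np.random.default_rng(seed)
        boxes = _random_boxes(rng, int(rng.integers(0, 15)))
        out = nms(boxes, 0.5)
        assert all(b in boxes for b in out)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                if a.class_name == b.class_name:
                    assert iou(a, b) < 0.5


class TestEnsemble:
    def test_single_model_equals_nms(self):
        rng = np.random.default_rng(7)
        boxes = _random_boxes(rng, 12)
        assert ensemble_detections([boxes], 0.5) == nms(boxes, 0.5)

    def test_duplicate_box_keeps_max_score(self):
        b_lo = _box(0, 0, 10, 10, score=0.6, src="m1")
        b_hi = _box(0, 0, 10, 10, score=0.8, src="m2")
        out = ensemble_detections([[b_lo], [b_hi]], 0.5)
        assert out == [b_hi] and out[0].source_model == "m2"

    def test_disjoint_models_union(self):
        a = [_box(0, 0, 5, 5, score=0.5)]
        b = [_box(50, 50, 60, 60, score=0.4)]
        assert len(ensemble_detections([a, b], 0.5)) == 2

    def test_k_copies_idempotent(self):
        rng = np.random.default_rng(9)
        boxes = _random_boxes(rng, 10)
        assert ensemble_detections([boxes] * 3, 0.5) == ensemble_detections([boxes], 0.5)

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_detections([], 0.5)


class TestBlobDetector:
    def test_uniform_image_no_boxes(self):
        assert blob_detect(np.full((64, 64), 0.3)) == []
        assert blob_detect(np.full((64, 64), 0.9)) == []

    def test_bright_square_within_one_pixel(self):
        img = np.full((64, 64), 0.1)
        img[20:30, 40:50] = 0.9
        (box,) = blob_detect(img)
        assert abs(box.x_min - 40) <= 1 and abs(box.x_max - 50) <= 1
        assert abs(box.y_min - 20) <= 1 and abs(box.y_max - 30) <= 1
        assert box.objectness == pytest.approx(0.9)

    def test_two_separated_squares(self):
        img = np.full((64, 64), 0.1)
        img[5:15, 5:15] = 0.8
        img[40:50, 40:50] = 0.7
        assert len(blob_detect(img)) == 2

    def test_min_area_filters_specks(self):
        img = np.full((64, 64), 0.1)
        img[10, 10] = 0.99
        assert blob_detect(img) == []


class TestDetectExam:
    def test_synthetic_abnormal_found_in_both_views(self):
        params = SynthParams(abnormal_fraction=1.0, seed=3)
        exam, gt = generate_exam(params, "S", "L", 3)
        boxes_cc, boxes_mlo = detect_exam(BlobDetector(), exam)
        for det, truth in ((boxes_cc, gt.boxes_cc), (boxes_mlo, gt.boxes_mlo)):
            masses = [b for b in det if b.class_name == "suspicious_mass"]
            assert masses
            assert max(iou(b, g) for b in masses for g in truth) >= 0.3

    def test_right_view_boxes_mapped_back(self):
        # A detection at mirrored column c maps back to width - c.
        params = SynthParams(abnormal_fraction=1.0, blob_count_range=(1, 1), seed=6)
        exam, gt = generate_exam(params, "S", "R", 6)
        boxes_cc, _ = detect_exam(BlobDetector(), exam)
        assert max(iou(b, g) for b in boxes_cc for g in gt.boxes_cc) >= 0.3

    def test_blank_views_no_boxes(self):
        exam, _ = generate_exam(SynthParams(abnormal_fraction=0.0, seed=4), "S", "L", 4)
        boxes_cc, boxes_mlo = detect_exam(BlobDetector(), exam)
        assert boxes_cc == [] and boxes_mlo == []


class TestMaxObjectness:
    def test_no_boxes_is_zero(self):
        assert max_objectness([], []) == 0.0

    def test_max_over_views(self):
        cc = [_box(0, 0, 5, 5, score=0.3)]
        mlo = [_box(0, 0, 5, 5, score=0.7)]
        assert max_objectness(cc, mlo) == 0.7

    def test_class_filtering(self):
        node = [_box(0, 0, 5, 5, score=0.9, cls="lymph_node")]
        assert max_objectness(node, [], "suspicious_mass") == 0.0
        assert max_objectness(node, [], "lymph_node") == 0.9


class TestYoloPredictions:
    def test_round_trip_against_writer(self, tmp_path):
        (tmp_path / "p.txt").write_text("0 0.5 0.5 0.2 0.2 0.75\n1 0.25 0.25 0.1 0.1\n")
        boxes = read_yolo_predictions(tmp_path / "p.txt", (100, 100))
        assert boxes[0].class_name == "suspicious_mass"
        assert boxes[0].objectness == 0.75
        assert boxes[0].as_tuple() == (40.0, 40.0, 60.0, 60.0)
        assert boxes[1].class_name == "lymph_node" and boxes[1].objectness == 1.0
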