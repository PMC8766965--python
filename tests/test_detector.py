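"""Sliding-window heat maps, box extraction, NMS and matching."""

import numpy as np
import pytest

from sbcnn.detector import (
    DetectionBox,
    HeatMap,
    extract_boxes,
    iou,
    match_detections,
    nms,
    normalize_and_threshold,
    sliding_window_heatmap,
)


def _const_classifier(value):
    return lambda patches: np.full(patches.shape[0], value)


class TestHeatmap:
    def test_single_window_constant(self):
        img = np.zeros((8, 8, 3))
        h = sliding_window_heatmap(img, _const_classifier(2.5), 8)
        assert np.all(h.grid == 2.5)

    def test_zero_classifier_zero_map(self):
        img = np.zeros((16, 16, 3))
        h = sliding_window_heatmap(img, _const_classifier(0.0), 8)
        assert np.all(h.grid == 0.0)

    def test_interior_coverage_is_four_at_half_overlap(self):
        """Interior pixels receive 2 windows per axis -> 4 contributions."""
        img = np.zeros((32, 32, 3))
        h = sliding_window_heatmap(img, _const_classifier(1.0), 8, overlap=0.5)
        inner = h.grid[8:-8, 8:-8]
        assert np.all(inner == 4.0)

    def test_linear_in_scores(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (24, 24, 3))
        scorer = lambda p: p.mean(axis=(1, 2, 3))
        h1 = sliding_window_heatmap(img, scorer, 8).grid
        h3 = sliding_window_heatmap(img, lambda p: 3 * scorer(p), 8).grid
        np.testing.assert_allclose(h3, 3 * h1)

    def test_window_too_large(self):
        with pytest.raises(ValueError, match="larger"):
            sliding_window_heatmap(np.zeros((8, 8, 3)), _const_classifier(1), 16)


class TestNormalizeThreshold:
    def test_two_level_map(self):
        h = HeatMap(grid=np.array([[0.0, 10.0]]), window=1, stride=1)
        assert np.array_equal(normalize_and_threshold(h, 0.5), [[0, 1]])

    def test_zero_threshold_all_ones(self):
        h = HeatMap(grid=np.array([[1.0, 2.0]]), window=1, stride=1)
        assert np.all(normalize_and_threshold(h, 0.0) == 1)

    def test_constant_map_all_zeros(self):
        h = HeatMap(grid=np.full((4, 4), 7.0), window=1, stride=1)
        assert np.all(normalize_and_threshold(h, 0.5) == 0)

    def test_idempotent_on_binary_map(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = HeatMap(grid=m, window=1, stride=1)
        assert np.array_equal(normalize_and_threshold(h, 0.5), m)


class TestExtractBoxes:
    def test_solid_rectangle_tight_halfopen_box(self):
        m = np.zeros((10, 12), dtype=np.uint8)
        m[2:6, 3:8] = 1  # rows 2..5, cols 3..7
        h = HeatMap(grid=m.astype(float), window=1, stride=1)
        boxes = extract_boxes(m, h)
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.x0, b.y0, b.x1, b.y1) == (3, 2, 8, 6)

    def test_empty_map(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        assert extract_boxes(m, HeatMap(grid=m.astype(float), window=1, stride=1)) == []

    def test_diagonal_pixels_single_component(self):
        """8-connectivity merges diagonal neighbours into one box."""
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1, 1] = m[2, 2] = 1
        boxes = extract_boxes(m, HeatMap(grid=m.astype(float), window=1, stride=1))
        assert len(boxes) == 1
        assert (boxes[0].x0, boxes[0].y0, boxes[0].x1, boxes[0].y1) == (1, 1, 3, 3)


class TestIou:
    def test_identical(self):
        b = DetectionBox(0, 0, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(DetectionBox(0, 0, 2, 2), DetectionBox(5, 5, 7, 7)) == 0.0

    def test_half_offset_unit_squares(self):
        a = DetectionBox(0.0, 0.0, 1.0, 1.0)
        b = DetectionBox(0.5, 0.0, 1.5, 1.0)
        assert abs(iou(a, b) - 1.0 / 3.0) < 1e-12

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            DetectionBox(2, 0, 2, 4)


def _brute_force_nms(boxes, threshold):
    """Reference greedy NMS written independently: explicit loops."""
    pool = sorted(boxes, key=lambda b: -b.score)
    kept = []
    while pool:
        best = pool[0]
        kept.append(best)
        survivors = []
        for b in pool[1:]:
            ix = max(0.0, min(best.x1, b.x1) - max(best.x0, b.x0))
            iy = max(0.0, min(best.y1, b.y1) - max(best.y0, b.y0))
            inter = ix * iy
            union = best.area + b.area - inter
            if (inter / union if union else 0.0) <= threshold:
                survivors.append(b)
        pool = survivors
    return kept


class TestNms:
    def test_duplicate_boxes_keep_highest(self):
        a = DetectionBox(0, 0, 4, 4, score=0.9)
        b = DetectionBox(0, 0, 4, 4, score=0.8)
        assert nms([a, b], 0.3) == [a]

    def test_disjoint_all_kept(self):
        boxes = [DetectionBox(5 * i, 0, 5 * i + 2, 2, score=i) for i in range(4)]
        assert len(nms(boxes, 0.3)) == 4

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(0, 12))
            boxes = []
            for _ in range(n):
                x0, y0 = rng.uniform(0, 20, 2)
                w, h = rng.uniform(1, 8, 2)
                boxes.append(DetectionBox(x0, y0, x0 + w, y0 + h, score=float(rng.uniform())))
            t = float(rng.uniform(0, 1))
            assert nms(boxes, t) == _brute_force_nms(boxes, t)

    def test_output_subset_with_bounded_pairwise_iou(self):
        rng = np.random.default_rng(2)
        boxes = [
            DetectionBox(x, y, x + 4, y + 4, score=float(rng.uniform()))
            for x, y in rng.uniform(0, 10, (30, 2))
        ]
        kept = nms(boxes, 0.3)
        assert all(b in boxes for b in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert iou(a, b) <= 0.3


def _brute_force_match(pred, truth, thr):
    order = sorted(range(len(pred)), key=lambda i: -pred[i].score)
    used = set()
    tp = 0
    for i in order:
        cands = [
            (iou(pred[i], truth[j]), j)
            for j in range(len(truth))
            if j not in used and iou(pred[i], truth[j]) >= thr
        ]
        if cands:
            _, j = max(cands)
            used.add(j)
            tp += 1
    return tp


class TestMatchDetections:
    def test_perfect_predictions(self):
        truth = [DetectionBox(0, 0, 4, 4), DetectionBox(10, 10, 14, 14)]
        pred = [DetectionBox(b.x0, b.y0, b.x1, b.y1, score=1.0) for b in truth]
        m = match_detections(pred, truth, 0.5)
        assert (m["tp"], m["fp"], m["fn"]) == (2, 0, 0)

    def test_no_predictions(self):
        truth = [DetectionBox(0, 0, 4, 4)]
        m = match_detections([], truth, 0.5)
        assert (m["tp"], m["fp"], m["fn"]) == (0, 0, 1)

    def test_brute_force_oracle_small_scenarios(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            def boxes(k):
                out = []
                for _ in range(k):
                    x0, y0 = rng.uniform(0, 10, 2)
                    w, h = rng.uniform(1, 6, 2)
                    out.append(DetectionBox(x0, y0, x0 + w, y0 + h, score=float(rng.uniform())))
                return out

            pred = boxes(int(rng.integers(0, 6)))
            truth = boxes(int(rng.integers(0, 6)))
            m = match_detections(pred, truth, 0.3)
            assert m["tp"] == _brute_force_match(pred, truth, 0.3)
            assert m["fp"] == len(pred) - m["tp"]
            assert m["fn"] == len(truth) - m["tp"]
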