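"""Sliding-window pathogen detection.

A patch classifier trained on positive/negative slices is slid over a
microscopy image with 50% overlap; its positive-class score is summed
over the pixels of each window into a heat map.  The heat map is min-max
normalized and thresholded into candidate regions, connected components
yield bounding boxes, and non-maximal suppression removes duplicates.

Boxes are 0-based, half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "DetectionBox",
    "HeatMap",
    "sliding_window_heatmap",
    "normalize_and_threshold",
    "extract_boxes",
    "iou",
    "nms",
    "match_detections",
    "detect",
    "make_patch_classifier",
]


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned half-open box with a detection score."""

    x0: float
    y0: float
    x1: float
    y1: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box {self}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class HeatMap:
    """Accumulated window-score grid, same size as the source image."""

    grid: np.ndarray
    window: int
    stride: int


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    """Start offsets along one axis; the last window snaps inside the image."""
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def sliding_window_heatmap(
    image: np.ndarray,
    classifier,
    window_size: int,
    overlap: float = 0.5,
    batch_size: int = 256,
) -> HeatMap:
    """Accumulate classifier scores over sliding windows.

    ``classifier`` maps a batch of patches (B, w, w, C) to positive-class
    scores (B,).  Each window's score is added to every pixel the window
    covers; stride = window * (1 - overlap), windows at the border are
    snapped inside the image.
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    if window_size > H or window_size > W:
        raise ValueError(f"window {window_size} larger than image {(H, W)}")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    stride = max(1, int(round(window_size * (1 - overlap))))
    ys = _window_starts(H, window_size, stride)
    xs = _window_starts(W, window_size, stride)
    coords = [(y, x) for y in ys for x in xs]
    grid = np.zeros((H, W), dtype=np.float64)
    for i in range(0, len(coords), batch_size):
        chunk = coords[i : i + batch_size]
        patches = np.stack([image[y : y + window_size, x : x + window_size] for y, x in chunk])
        scores = np.asarray(classifier(patches), dtype=np.float64)
        for (y, x), s in zip(chunk, scores):
            grid[y : y + window_size, x : x + window_size] += s
    return HeatMap(grid=grid, window=window_size, stride=stride)


def normalize_and_threshold(h: HeatMap, t: float = 0.5) -> np.ndarray:
    """Min-max normalize the heat map to [0, 1] and binarize at ``t``.

    A constant map normalizes to all zeros (nothing stands out).
    """
    if not (0 <= t <= 1):
        raise ValueError("threshold must be in [0, 1]")
    g = h.grid
    lo, hi = g.min(), g.max()
    if hi == lo:
        norm = np.zeros_like(g)
    else:
        norm = (g - lo) / (hi - lo)
    return (norm >= t).astype(np.uint8)


def _normalized(h: HeatMap) -> np.ndarray:
    g = h.grid
    lo, hi = g.min(), g.max()
    return np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)


def extract_boxes(binary_map: np.ndarray, heat: HeatMap) -> list[DetectionBox]:
    """Boxes of 8-connected components; score = mean normalized heat inside."""
    labelled = measure.label(binary_map, connectivity=2)
    norm = _normalized(heat)
    boxes = []
    for region in measure.regionprops(labelled):
        y0, x0, y1, x1 = region.bbox
        score = float(norm[labelled == region.label].mean())
        boxes.append(DetectionBox(x0=x0, y0=y0, x1=x1, y1=y1, score=score))
    return boxes


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two half-open boxes, in [0, 1]."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def nms(boxes: list[DetectionBox], iou_threshold: float = 0.3) -> list[DetectionBox]:
    """Greedy non-maximal suppression in descending score order.

    Keeps the highest-scoring box, drops every box with IoU strictly above
    the threshold against a kept box, and repeats.
    """
    if not (0 <= iou_threshold <= 1):
        raise ValueError("iou_threshold must be in [0, 1]")
    remaining = sorted(boxes, key=lambda b: -b.score)
    kept: list[DetectionBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if iou(best, b) <= iou_threshold]
    return kept


def match_detections(
    pred: list[DetectionBox],
    truth: list[DetectionBox],
    iou_threshold: float = 0.3,
) -> dict:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending score order; each is a true
    positive iff its best-IoU unmatched truth box reaches the threshold.
    Returns TP/FP/FN counts plus per-detection (score, is_tp) labels.
    """
    if not (0 <= iou_threshold <= 1):
        raise ValueError("iou_threshold must be in [0, 1]")
    order = sorted(range(len(pred)), key=lambda i: -pred[i].score)
    matched = [False] * len(truth)
    labels = [None] * len(pred)
    tp = 0
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truth):
            if matched[j]:
                continue
            v = iou(pred[i], t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            labels[i] = (pred[i].score, True)
            tp += 1
        else:
            labels[i] = (pred[i].score, False)
    return {
        "tp": tp,
        "fp": len(pred) - tp,
        "fn": len(truth) - tp,
        "labels": labels,
    }


def detect(
    image: np.ndarray,
    classifier,
    window_size: int,
    overlap: float = 0.5,
    threshold: float = 0.5,
    nms_iou: float = 0.3,
) -> tuple[list[DetectionBox], HeatMap]:
    """Full pipeline: heat map -> threshold -> boxes -> NMS."""
    heat = sliding_window_heatmap(image, classifier, window_size, overlap)
    binary = normalize_and_threshold(heat, threshold)
    boxes = extract_boxes(binary, heat)
    return nms(boxes, nms_iou), heat


def _area_downsample(patches: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool (B, H, W, C) patches by an integer factor."""
    if factor == 1:
        return patches
    B, H, W, C = patches.shape
    return patches.reshape(B, H // factor, factor, W // factor, factor, C).mean(axis=(2, 4))


def make_patch_classifier(model, n_pre: int, rng, downsample: int = 1, hard: bool = True):
    """Adapt an exported SBCNN into a window classifier for the detector.

    Windows are area-downsampled by ``downsample`` to the model's input
    size.  The returned score is the classifier's positive decision (1 if
    the positive class wins, else 0), so the heat map counts how many of
    the overlapping windows covering a pixel voted positive — a scale
    that is comparable across objects, unlike the raw integer margin,
    whose magnitude varies with how centered an object happens to sit in
    its windows.  Pass ``hard=False`` for the raw clipped margin instead.
    """

    def classify(patches: np.ndarray) -> np.ndarray:
        x = _area_downsample(np.asarray(patches, dtype=np.float64), downsample)
        scores = model.infer(x, n_pre, rng)
        margin = (scores[:, 1] - scores[:, 0]).astype(np.float64)
        if hard:
            return (margin > 0).astype(np.float64)
        return np.maximum(margin, 0.0)

    return classify
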