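"""Synthetic microscopy scenes, slice datasets and classification sets.

The scene generator plants small high-contrast objects (disk-like
parasites, rod-like bacilli, or larger egg-like ellipses) on a textured
background and returns exact ground-truth boxes — a statistical stand-in
for annotated thick-smear / sputum / stool-slide microscopy, not an
attempt at photorealism.  Scenes are sliced into positive patches
(centered on objects, augmented by the 8 dihedral transforms) and
negative patches (random crops disjoint from every object), with random
discarding of negatives to rebalance the heavily skewed class ratio.

A separate generator produces a small multi-class RGB classification set
(smooth per-class color/texture templates plus pixel noise) for
presentation-strategy experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detector import DetectionBox, iou
from .sbcnn_model import ClassificationDataset

__all__ = [
    "SceneSpec",
    "SliceDataset",
    "generate_scene",
    "generate_scenes",
    "make_slices",
    "generate_classification_set",
    "make_classification_dataset",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic microscopy scene.

    ``contrast`` is the Mahalanobis distance of the object color from the
    background mean in units of the (isotropic) background pixel noise;
    objects are undetectable by construction at contrast 0, so it must be
    positive.
    """

    size: tuple[int, int] = (130, 130)
    bg_mean: tuple[float, float, float] = (180.0, 150.0, 170.0)
    noise_std: float = 10.0
    mottle_amp: float = 8.0
    mottle_scale: int = 16
    object_shape: str = "dot"  # dot | rod | ellipse
    n_objects: int = 6
    size_range: tuple[int, int] = (10, 16)
    contrast: float = 6.0
    min_separation: int = 12  # gap (px) between object boxes; pathogens are sparse
    border_margin: int = 12  # objects inset from the field edge (vignetting zone)
    max_tries: int = 200

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0 (objects must be detectable)")
        if self.size_range[1] >= min(self.size):
            raise ValueError("object sizes must be smaller than the image")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.object_shape not in ("dot", "rod", "ellipse"):
            raise ValueError(f"unknown object shape {self.object_shape!r}")


@dataclass
class SliceDataset:
    """Patch dataset produced by slicing scenes."""

    patches: np.ndarray  # (N, H, W, 3)
    labels: np.ndarray  # 1 = positive, 0 = negative
    source_boxes: list
    ratio_before: float  # positives : negatives before rebalancing
    ratio_after: float


def _object_mask(shape: str, size: int, angle: float) -> np.ndarray:
    """Boolean mask of one object on a (size, size) canvas."""
    r = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    if shape == "dot":
        return xx**2 + yy**2 <= r**2
    if shape == "rod":
        half_len, half_w = r, max(1.0, r / 3.0)
        return (np.abs(u) <= half_len) & (np.abs(v) <= half_w)
    # ellipse
    return (u / r) ** 2 + (v / (r / 2.0)) ** 2 <= 1.0


def generate_scene(spec: SceneSpec, rng: np.random.Generator):
    """One scene: (image (H, W, 3) float in [0, 255], ground-truth boxes).

    Objects are placed without overlap; placement failure after
    ``max_tries`` attempts raises with a suggestion to lower the count.
    Identical seeds give identical scenes.
    """
    H, W = spec.size
    img = np.empty((H, W, 3), dtype=np.float64)
    # low-frequency mottling: coarse noise smoothed up to scene scale
    coarse = rng.standard_normal((H // spec.mottle_scale + 2, W // spec.mottle_scale + 2, 3))
    mottle = ndimage.zoom(coarse, (spec.mottle_scale, spec.mottle_scale, 1), order=1)[:H, :W]
    img[:] = np.asarray(spec.bg_mean) + spec.mottle_amp * mottle

    boxes: list[DetectionBox] = []
    for _ in range(spec.n_objects):
        placed = False
        for _try in range(spec.max_tries):
            size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
            bm = spec.border_margin
            y0 = int(rng.integers(bm, H - size - bm + 1))
            x0 = int(rng.integers(bm, W - size - bm + 1))
            m = spec.min_separation
            cand = DetectionBox(x0=x0, y0=y0, x1=x0 + size, y1=y0 + size)
            grown = DetectionBox(x0=x0 - m, y0=y0 - m, x1=x0 + size + m, y1=y0 + size + m)
            if all(iou(grown, b) == 0.0 for b in boxes):
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                color = np.asarray(spec.bg_mean) + spec.contrast * spec.noise_std * direction
                mask = _object_mask(spec.object_shape, size, rng.uniform(0, np.pi))
                region = img[y0 : y0 + size, x0 : x0 + size]
                region[mask] = color
                boxes.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_objects} non-overlapping objects in {spec.size}; "
                "lower n_objects or enlarge the scene"
            )
    img += rng.normal(0.0, spec.noise_std, img.shape)
    return np.clip(img, 0.0, 255.0), boxes


def generate_scenes(spec: SceneSpec, n_scenes: int, rng: np.random.Generator):
    """A list of (image, boxes) scenes from one spec."""
    return [generate_scene(spec, rng) for _ in range(n_scenes)]


_DIHEDRAL = [
    lambda p: p,
    lambda p: np.rot90(p, 1, axes=(0, 1)),
    lambda p: np.rot90(p, 2, axes=(0, 1)),
    lambda p: np.rot90(p, 3, axes=(0, 1)),
    lambda p: p[:, ::-1],
    lambda p: np.rot90(p[:, ::-1], 1, axes=(0, 1)),
    lambda p: np.rot90(p[:, ::-1], 2, axes=(0, 1)),
    lambda p: np.rot90(p[:, ::-1], 3, axes=(0, 1)),
]


def _area_downsample(patch: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return patch
    H, W, C = patch.shape
    return patch.reshape(H // factor, factor, W // factor, factor, C).mean(axis=(1, 3))


def make_slices(
    scenes,
    patch_size: int = 20,
    downsample: int = 2,
    neg_keep_prob: float = 0.5,
    augment: bool = True,
    rng: np.random.Generator | None = None,
    neg_candidates_per_scene: int | None = None,
    neg_max_tries: int = 50,
    jitter: bool = True,
) -> SliceDataset:
    """Positive/negative slice dataset from annotated scenes.

    Positive patches are centered crops on each ground-truth box (crop
    edge = patch_size * downsample, area-averaged down to patch_size),
    expanded by the 8 dihedral transforms when ``augment``.  With
    ``jitter`` each dihedral copy is offset by a small random shift
    bounded so the patch center stays inside the ground-truth box — this
    exposes the classifier to the off-center views a sliding window
    produces.  Negative patches are random crops with zero IoU against
    every box, kept with probability ``neg_keep_prob``.  The candidate
    negative count defaults to an oversampled grid (16 per object) to
    emulate the raw skew of microscopy fields before rebalancing; with
    the default keep probability this roughly balances the 8x-augmented
    positives.
    """
    rng = rng or np.random.default_rng()
    crop = patch_size * downsample
    patches, labels = [], []
    source_boxes = []
    n_pos_raw = 0
    n_neg_candidates = 0
    n_neg_kept = 0
    for img, boxes in scenes:
        H, W = img.shape[:2]
        if crop > H or crop > W:
            raise ValueError(f"crop {crop} does not fit in scene {(H, W)}")
        for box in boxes:
            cy = int((box.y0 + box.y1) // 2)
            cx = int((box.x0 + box.x1) // 2)
            # jitter bound keeps the (jittered) patch center inside the box
            # and the object dominant in the patch (<= patch quarter-size)
            jy = min(int(box.y1 - box.y0) // 2, patch_size // 4) if jitter else 0
            jx = min(int(box.x1 - box.x0) // 2, patch_size // 4) if jitter else 0
            n_pos_raw += 1
            transforms = _DIHEDRAL if augment else _DIHEDRAL[:1]
            for f in transforms:
                dy = int(rng.integers(-jy, jy + 1)) if jy else 0
                dx = int(rng.integers(-jx, jx + 1)) if jx else 0
                y0 = int(np.clip(cy + dy - crop // 2, 0, H - crop))
                x0 = int(np.clip(cx + dx - crop // 2, 0, W - crop))
                patch = img[y0 : y0 + crop, x0 : x0 + crop]
                patches.append(_area_downsample(np.ascontiguousarray(f(patch)), downsample))
                labels.append(1)
                source_boxes.append(box)
        n_cand = neg_candidates_per_scene or 16 * max(1, len(boxes))
        for _ in range(n_cand):
            for _try in range(neg_max_tries):
                y0 = int(rng.integers(0, H - crop + 1))
                x0 = int(rng.integers(0, W - crop + 1))
                cand = DetectionBox(x0=x0, y0=y0, x1=x0 + crop, y1=y0 + crop)
                if all(iou(cand, b) == 0.0 for b in boxes):
                    break
            else:
                raise RuntimeError("no valid negative location found; scene too crowded")
            n_neg_candidates += 1
            if rng.uniform() < neg_keep_prob:
                n_neg_kept += 1
                patch = img[y0 : y0 + crop, x0 : x0 + crop]
                patches.append(_area_downsample(patch, downsample))
                labels.append(0)
                source_boxes.append(None)
    ratio_before = n_pos_raw / max(1, n_neg_candidates)
    ratio_after = (labels.count(1)) / max(1, labels.count(0))
    return SliceDataset(
        patches=np.stack(patches),
        labels=np.asarray(labels, dtype=np.int64),
        source_boxes=source_boxes,
        ratio_before=ratio_before,
        ratio_after=ratio_after,
    )


def generate_classification_set(
    n_classes: int = 4,
    n_per_class: int = 100,
    image_size: int = 12,
    separation: float = 4.0,
    noise_std: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Small multi-class RGB set: smooth class templates plus pixel noise.

    Templates are smooth random color/texture fields with pairwise
    root-mean-square distance ``separation`` (in the same units as
    ``noise_std``); samples add iid pixel noise, so the Bayes error
    shrinks as separation / noise_std grows.  Returns (images, labels)
    with images (N, H, W, 3) in [0, 255].
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = rng or np.random.default_rng()
    H = image_size
    templates = []
    for _ in range(n_classes):
        f = ndimage.gaussian_filter(rng.standard_normal((H, H, 3)), sigma=(H / 6, H / 6, 0))
        f /= np.sqrt((f**2).mean())  # unit per-pixel RMS
        # independent unit fields sit at RMS distance ~sqrt(2); rescale so
        # the expected pairwise distance equals `separation`
        templates.append(128.0 + (separation / np.sqrt(2.0)) * f)
    images, labels = [], []
    for c, tpl in enumerate(templates):
        batch = np.broadcast_to(tpl, (n_per_class, H, H, 3)).copy()
        if noise_std > 0:
            batch += rng.normal(0.0, noise_std, batch.shape)
        images.append(np.clip(batch, 0.0, 255.0))
        labels.append(np.full(n_per_class, c, dtype=np.int64))
    images = np.concatenate(images)
    labels = np.concatenate(labels)
    order = rng.permutation(images.shape[0])
    return images[order], labels[order]


def make_classification_dataset(
    n_classes: int = 4,
    n_train_per_class: int = 60,
    n_test_per_class: int = 40,
    image_size: int = 12,
    separation: float = 4.0,
    noise_std: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ClassificationDataset:
    """Train/test split drawn from one set of class templates."""
    rng = rng or np.random.default_rng()
    n = n_train_per_class + n_test_per_class
    images, labels = generate_classification_set(
        n_classes, n, image_size, separation, noise_std, rng
    )
    train_idx, test_idx = [], []
    seen = {c: 0 for c in range(n_classes)}
    for i, lab in enumerate(labels):
        if seen[int(lab)] < n_train_per_class:
            train_idx.append(i)
            seen[int(lab)] += 1
        else:
            test_idx.append(i)
    return ClassificationDataset(
        train_images=images[train_idx],
        train_labels=labels[train_idx],
        test_images=images[test_idx],
        test_labels=labels[test_idx],
    )
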