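"""Canned desk-scale experiments tying the pipeline together.

Two studies are packaged here with fixed conditions so they can be rerun
identically from the test suite, the CLI and the reproduction script:

* ``strategy_experiment`` — matched- vs max-presentations on the
  synthetic multi-class set (the desk-scale analogue of the CIFAR-10
  presentation study, averaged over 5 trials).
* ``detection_experiment`` — train a reduced SBCNN patch classifier on
  slices of synthetic microscopy scenes, run the sliding-window detector
  on held-out scenes and report mAP at IoU 0.3.

Problem sizes are chosen so each study completes in minutes on one CPU
core; the conditions (class count, noise, scene geometry, N_pre) are
fixed as part of the study design and documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detector import detect, make_patch_classifier, match_detections
from .evaluation import detection_pr_map
from .sbcnn_model import (
    SBCNN,
    ClassificationDataset,
    PresentationConfig,
    build_mini_sbcnn,
    evaluate_strategies,
    train,
)
from .stochastic_input import compute_channel_stats
from .synthetic_data import SceneSpec, generate_scenes, make_classification_dataset, make_slices

__all__ = ["strategy_experiment", "detection_experiment", "train_patch_classifier"]

# conditions of the presentation-strategy study
STRATEGY_N_GRID = (2, 8, 32)
STRATEGY_NOISE_STD = 2.0
STRATEGY_SEPARATION = 4.0
STRATEGY_OPT = {"epochs": 6, "lr": 5e-3, "batch_size": 64}

# conditions of the detection study
DETECT_N_PRE = 32
DETECT_WINDOW = 12
DETECT_OPT = {"epochs": 10, "lr": 5e-3, "batch_size": 64}


def strategy_experiment(
    base_seed: int = 0,
    n_trials: int = 5,
    n_grid=STRATEGY_N_GRID,
    dist: str = "normal",
) -> pd.DataFrame:
    """Matched vs max presentations on the synthetic classification set.

    Four smooth-template classes at 12x12 RGB, 60 train / 40 test images
    per class, template separation 4 and pixel noise 2 (a task hard
    enough that a two-presentation input stream visibly hurts).  Returns
    the aggregated metric table from :func:`evaluate_strategies`.
    """
    rng = np.random.default_rng(base_seed)
    ds = make_classification_dataset(
        n_classes=4,
        n_train_per_class=60,
        n_test_per_class=40,
        image_size=12,
        separation=STRATEGY_SEPARATION,
        noise_std=STRATEGY_NOISE_STD,
        rng=rng,
    )
    stats = compute_channel_stats(ds.train_images)
    spec = build_mini_sbcnn(ds.num_classes, input_size=12, width=12)

    def factory(seed: int) -> SBCNN:
        return SBCNN(spec, stats, dist=dist, seed=seed)

    return evaluate_strategies(
        factory,
        ds,
        n_grid=list(n_grid),
        n_trials=n_trials,
        base_seed=base_seed,
        optimizer_cfg=dict(STRATEGY_OPT),
    )


def train_patch_classifier(
    train_scenes,
    seed: int,
    n_pre: int = DETECT_N_PRE,
    patch_size: int = DETECT_WINDOW,
    width: int = 24,
    dist: str = "normal",
    optimizer_cfg: dict | None = None,
):
    """Train a reduced SBCNN on slices of the given scenes; returns the
    exported model and the slice dataset."""
    rng = np.random.default_rng(seed)
    slices = make_slices(
        train_scenes, patch_size=patch_size, downsample=1, neg_keep_prob=0.5, rng=rng
    )
    ds = ClassificationDataset(
        slices.patches, slices.labels, slices.patches[:1], slices.labels[:1]
    )
    stats = compute_channel_stats(slices.patches)
    spec = build_mini_sbcnn(2, input_size=patch_size, width=width, reduced=True)
    model = SBCNN(spec, stats, dist=dist, seed=seed)
    opt = dict(DETECT_OPT)
    opt.update(optimizer_cfg or {})
    opt["seed"] = seed
    train(model, ds, PresentationConfig.matched(n_pre), opt)
    return model.export(), slices


def detection_experiment(
    seed: int = 0,
    n_train_scenes: int = 45,
    n_test_scenes: int = 20,
    n_pre: int = DETECT_N_PRE,
    iou_threshold: float = 0.3,
) -> dict:
    """End-to-end sliding-window detection on synthetic microscopy scenes.

    Scenes are 132x132 fields with six planted high-contrast objects
    each; the patch classifier is trained on slices of the training
    scenes (matched presentations, N_pre = 32 as in the full-scale
    detector) and evaluated on held-out scenes.  Returns mAP at the given
    IoU plus detection counts.
    """
    rng = np.random.default_rng(seed)
    scene_spec = SceneSpec(size=(132, 132))
    train_scenes = generate_scenes(scene_spec, n_train_scenes, rng)
    test_scenes = generate_scenes(scene_spec, n_test_scenes, rng)
    model, _ = train_patch_classifier(train_scenes, seed=seed, n_pre=n_pre)
    classifier = make_patch_classifier(
        model, n_pre, np.random.default_rng(seed + 1000), downsample=1
    )
    scores, is_tp = [], []
    n_truth = 0
    for img, boxes in test_scenes:
        pred, _ = detect(img, classifier, window_size=DETECT_WINDOW)
        matched = match_detections(pred, boxes, iou_threshold=iou_threshold)
        for s, tp in matched["labels"]:
            scores.append(s)
            is_tp.append(tp)
        n_truth += len(boxes)
    _, _, ap = detection_pr_map(np.asarray(scores), np.asarray(is_tp), n_truth)
    return {
        "map": ap,
        "n_truth": n_truth,
        "n_detections": len(scores),
        "tp": int(np.sum(is_tp)),
        "fp": int(len(scores) - np.sum(is_tp)),
        "iou_threshold": iou_threshold,
        "n_pre": n_pre,
    }
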