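"""Stochastic binarized CNN: architecture specs, training, inference.

The model family is an AlexNet-style binarized CNN whose first layer
consumes stochastic binary presentations of the input instead of int8 /
float pixels.  Inference follows the fully binarized pipeline:

    stochastic layer:  a_n = sign(popcount(XNOR(W0, X > rand)) - b0)
                       A_0 = sign(sum_n a_n)          (n = 1..N_pre)
    regular layers:    A_i = sign(popcount(XNOR(W_i, A_{i-1})) - b_i)

Training uses real-valued shadow weights with a binarized forward pass and
straight-through-estimator gradients (Adam optimizer); batch norm follows
every binarized conv/fc layer during training and is folded into integer
popcount thresholds at export, so exported inference is integer-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .binary_core import fold_batchnorm
from .stochastic_input import (
    ChannelStats,
    normalize,
    rescale_minmax,
    sample_presentations,
)

__all__ = [
    "ConvSpec",
    "PoolSpec",
    "FCSpec",
    "BNSpec",
    "ActSpec",
    "FlattenSpec",
    "NetworkSpec",
    "PresentationConfig",
    "ClassificationDataset",
    "build_alexnet",
    "build_mini_sbcnn",
    "SBCNN",
    "ExportedLayer",
    "ExportedSBCNN",
    "aggregate_presentations",
    "sbcnn_infer",
    "train",
    "evaluate_strategies",
]


# ----------------------------------------------------------------------
# Layer / network descriptors


@dataclass(frozen=True)
class ConvSpec:
    in_ch: int
    out_ch: int
    kernel: int
    stride: int = 1
    pad: int = 0
    bias: bool = True
    precision: str = "binary"  # fp32 | int8 | binary
    kind: str = "conv"


@dataclass(frozen=True)
class PoolSpec:
    kernel: int
    stride: int
    kind: str = "pool"


@dataclass(frozen=True)
class FCSpec:
    in_f: int
    out_f: int
    bias: bool = True
    precision: str = "binary"
    kind: str = "fc"


@dataclass(frozen=True)
class BNSpec:
    features: int
    kind: str = "batchnorm"


@dataclass(frozen=True)
class ActSpec:
    activation: str = "binary"
    kind: str = "activation"


@dataclass(frozen=True)
class FlattenSpec:
    kind: str = "flatten"


@dataclass
class NetworkSpec:
    """Ordered layer descriptors; drives model building and cost analysis."""

    layers: list
    input_shape: tuple[int, int, int]  # (C, H, W)
    num_classes: int

    def output_shapes(self) -> list[tuple]:
        """Shape after each layer; validates that shapes chain."""
        c, h, w = self.input_shape
        shapes = []
        flat = None
        for layer in self.layers:
            if layer.kind == "conv":
                if flat is not None or layer.in_ch != c:
                    raise ValueError(f"conv in_ch {layer.in_ch} does not chain from {c} channels")
                h = (h + 2 * layer.pad - layer.kernel) // layer.stride + 1
                w = (w + 2 * layer.pad - layer.kernel) // layer.stride + 1
                c = layer.out_ch
                shapes.append((c, h, w))
            elif layer.kind == "pool":
                h = (h - layer.kernel) // layer.stride + 1
                w = (w - layer.kernel) // layer.stride + 1
                shapes.append((c, h, w))
            elif layer.kind == "flatten":
                flat = c * h * w
                shapes.append((flat,))
            elif layer.kind == "fc":
                if flat is None:
                    flat = c * h * w
                if layer.in_f != flat:
                    raise ValueError(f"fc in_f {layer.in_f} does not chain from {flat}")
                flat = layer.out_f
                shapes.append((flat,))
            else:  # batchnorm / activation keep shape
                shapes.append((c, h, w) if flat is None else (flat,))
        return shapes

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "num_classes": self.num_classes,
                "layers": [asdict(l) for l in self.layers],
            }
        )


@dataclass
class PresentationConfig:
    """Presentation counts for training and inference.

    ``matched`` trains and infers with the same N_pre; ``max`` trains at
    the maximum presentation count (256 by default) and infers at
    ``n_infer``.
    """

    n_train: int
    n_infer: int
    strategy: str = "matched"

    MAX_TRAIN: int = 256

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_infer < 1:
            raise ValueError("presentation counts must be >= 1")
        if self.strategy == "matched":
            if self.n_train != self.n_infer:
                raise ValueError("matched strategy requires n_train == n_infer")
        elif self.strategy != "max":
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @classmethod
    def matched(cls, n: int) -> "PresentationConfig":
        return cls(n_train=n, n_infer=n, strategy="matched")

    @classmethod
    def max_presentations(cls, n_infer: int, n_train: int | None = None) -> "PresentationConfig":
        return cls(n_train=n_train or cls.MAX_TRAIN, n_infer=n_infer, strategy="max")


@dataclass
class ClassificationDataset:
    """Images (N, H, W, C) with integer labels, split into train and test."""

    train_images: np.ndarray
    train_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray

    @property
    def num_classes(self) -> int:
        return int(max(self.train_labels.max(), self.test_labels.max())) + 1


# ----------------------------------------------------------------------
# Architecture builders


def build_alexnet(num_classes: int, reduced: bool = False) -> NetworkSpec:
    """AlexNet-style spec: full variant, or reduced (one 4096x4096 fc removed).

    The full variant at 224x224 input carries 57,012,034 parameters for 2
    classes; the reduced variant drops the 16,781,312-parameter hidden fc.
    Batch norm and binary activations follow each conv/fc during training
    and are folded away at export, so they carry no weight memory.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    layers: list = [
        ConvSpec(3, 64, 11, stride=4, pad=2),
        BNSpec(64), ActSpec(),
        PoolSpec(3, 2),
        ConvSpec(64, 192, 5, pad=2),
        BNSpec(192), ActSpec(),
        PoolSpec(3, 2),
        ConvSpec(192, 384, 3, pad=1),
        BNSpec(384), ActSpec(),
        ConvSpec(384, 256, 3, pad=1),
        BNSpec(256), ActSpec(),
        ConvSpec(256, 256, 3, pad=1),
        BNSpec(256), ActSpec(),
        PoolSpec(3, 2),
        FlattenSpec(),
        FCSpec(9216, 4096),
        BNSpec(4096), ActSpec(),
    ]
    if not reduced:
        layers += [FCSpec(4096, 4096), BNSpec(4096), ActSpec()]
    layers += [FCSpec(4096, num_classes)]
    return NetworkSpec(layers=layers, input_shape=(3, 224, 224), num_classes=num_classes)


def build_mini_sbcnn(
    num_classes: int,
    input_size: int = 20,
    width: int = 16,
    reduced: bool = True,
) -> NetworkSpec:
    """Small-input SBCNN spec for patch classifiers and desk-scale studies.

    Two binarized conv stages with 2x pooling, then a hidden binarized fc
    (omitted when ``reduced``) and a binary output layer.  ``input_size``
    must be divisible by 4.
    """
    if input_size % 4:
        raise ValueError("input_size must be divisible by 4")
    s2 = input_size // 2
    s4 = input_size // 4
    layers: list = [
        ConvSpec(3, width, 3, pad=1, bias=False),
        BNSpec(width), ActSpec(),
        PoolSpec(2, 2),
        ConvSpec(width, 2 * width, 3, pad=1, bias=False),
        BNSpec(2 * width), ActSpec(),
        PoolSpec(2, 2),
        FlattenSpec(),
    ]
    flat = 2 * width * s4 * s4
    if not reduced:
        layers += [FCSpec(flat, 4 * width, bias=False), BNSpec(4 * width), ActSpec()]
        flat = 4 * width
    layers += [FCSpec(flat, num_classes, bias=False)]
    return NetworkSpec(layers=layers, input_shape=(3, input_size, input_size), num_classes=num_classes)


# ----------------------------------------------------------------------
# Trainable model


class SBCNN:
    """Trainable stochastic binarized CNN built from a :class:`NetworkSpec`.

    The first conv + batchnorm + sign block forms the stochastic stem
    applied per presentation; its sign outputs are aggregated across
    presentations (sign of the mean, ties to +1) before the remaining
    binarized layers run once.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        stats: ChannelStats,
        dist: str = "normal",
        seed: int = 0,
    ):
        self.spec = spec
        self.stats = stats
        self.dist = dist
        rng = np.random.default_rng(seed)
        spec.output_shapes()  # validate chaining

        stem_layers: list[nn.Layer] = []
        trunk_layers: list[nn.Layer] = []
        target = stem_layers
        seen_act = False
        for layer in spec.layers:
            if layer.kind == "conv":
                target.append(
                    nn.BinConv2d(
                        layer.in_ch, layer.out_ch, layer.kernel, layer.stride, layer.pad,
                        binary=layer.precision == "binary", rng=rng,
                    )
                )
            elif layer.kind == "fc":
                target.append(nn.BinLinear(layer.in_f, layer.out_f, binary=layer.precision == "binary", rng=rng))
            elif layer.kind == "batchnorm":
                target.append(nn.BatchNorm(layer.features))
            elif layer.kind == "activation":
                target.append(nn.SignAct())
                if not seen_act:
                    seen_act = True
                    target = trunk_layers
            elif layer.kind == "pool":
                if layer.kernel != layer.stride:
                    raise ValueError("only non-overlapping pooling is supported at runtime")
                target.append(nn.MaxPool2d(layer.kernel))
            elif layer.kind == "flatten":
                target.append(nn.Flatten())
        self.stem = nn.Sequential(stem_layers)
        self.agg = nn.PresentationAggregate(n_pre=1)
        self.trunk = nn.Sequential(trunk_layers)
        out = spec.layers[-1]
        self.score_scale = 1.0 / np.sqrt(out.in_f)

    def params(self):
        return self.stem.params() + self.trunk.params()

    # -- forward --------------------------------------------------------
    def sample_inputs(self, images: np.ndarray, n_pre: int, rng) -> np.ndarray:
        """Raw images (B, H, W, C) -> +/-1 presentations (B*N, C, H, W)."""
        if self.dist == "uniform":
            x = rescale_minmax(images, self.stats)
        else:
            x = normalize(images, self.stats)
        bits = sample_presentations(x, n_pre, dist=self.dist, rng=rng)  # (N,B,H,W,C)
        pm1 = bits.astype(nn.DTYPE) * nn.DTYPE(2.0) - nn.DTYPE(1.0)
        pm1 = pm1.transpose(1, 0, 4, 2, 3)  # (B, N, C, H, W)
        return np.ascontiguousarray(pm1.reshape(-1, *pm1.shape[2:]))

    def forward_scores(
        self,
        images: np.ndarray,
        n_pre: int,
        rng: np.random.Generator,
        train: bool = False,
        presentations: np.ndarray | None = None,
    ) -> np.ndarray:
        if n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        x = presentations if presentations is not None else self.sample_inputs(images, n_pre, rng)
        self.agg.n_pre = n_pre
        h = self.stem.forward(x, train)
        a = self.agg.forward(h, train)
        return self.trunk.forward(a, train)

    def backward(self, dscores: np.ndarray) -> None:
        g = self.trunk.backward(dscores)
        g = self.agg.backward(g)
        self.stem.backward(g)

    # -- export ---------------------------------------------------------
    def export(self) -> "ExportedSBCNN":
        """Fold batch norm into integer thresholds; returns the integer model."""
        stem_exp = _export_block(self.stem.layers)
        trunk_exp = _export_block(self.trunk.layers)
        return ExportedSBCNN(
            stem=stem_exp,
            trunk=trunk_exp,
            stats=self.stats,
            dist=self.dist,
            spec_json=self.spec.to_json(),
            num_classes=self.spec.num_classes,
        )


def _export_block(layers: list[nn.Layer]) -> list["ExportedLayer"]:
    out: list[ExportedLayer] = []
    i = 0
    while i < len(layers):
        layer = layers[i]
        if isinstance(layer, (nn.BinConv2d, nn.BinLinear)):
            W = np.where(layer.W.data >= 0, 1.0, -1.0).astype(np.float64)
            if isinstance(layer, nn.BinConv2d):
                meta = {"kind": "conv", "stride": layer.stride, "pad": layer.pad,
                        "kernel": layer.k, "in_ch": layer.in_ch, "out_ch": layer.out_ch}
                fan_in = layer.in_ch * layer.k * layer.k
            else:
                meta = {"kind": "fc", "in_f": layer.in_f, "out_f": layer.out_f}
                fan_in = layer.in_f
            bn = layers[i + 1] if i + 1 < len(layers) and isinstance(layers[i + 1], nn.BatchNorm) else None
            if bn is not None:
                out.append(
                    ExportedLayer.folded(
                        meta, W, fan_in,
                        gamma=bn.gamma.data, beta=bn.beta.data,
                        mean=bn.running_mean, var=bn.running_var, eps=bn.eps,
                    )
                )
                i += 3  # conv/fc + bn + sign
            else:
                out.append(ExportedLayer(meta=meta, W=W, fan_in=fan_in))
                i += 1
        elif isinstance(layer, nn.MaxPool2d):
            out.append(ExportedLayer(meta={"kind": "pool", "kernel": layer.k}, W=None, fan_in=0))
            i += 1
        elif isinstance(layer, nn.Flatten):
            out.append(ExportedLayer(meta={"kind": "flatten"}, W=None, fan_in=0))
            i += 1
        else:
            raise ValueError(f"cannot export layer {type(layer).__name__} at position {i}")
    return out


# ----------------------------------------------------------------------
# Exported integer model


@dataclass
class ExportedLayer:
    """One exported layer: +/-1 weights and integer firing thresholds.

    ``theta`` is the dot-product-domain threshold (theta = 2b - n): the
    channel fires +1 iff w . x >= theta, equivalently iff
    popcount(XNOR) >= b.  The pre-fold batch-norm parameters are retained
    for the float reference path.
    """

    meta: dict
    W: np.ndarray | None
    fan_in: int
    theta: np.ndarray | None = None
    b: np.ndarray | None = None
    bn: dict | None = None

    @classmethod
    def folded(cls, meta, W, fan_in, gamma, beta, mean, var, eps=1e-5):
        b, flip = fold_batchnorm(gamma, beta, mean, var, fan_in, eps=eps)
        Wm = W.reshape(W.shape[0], -1).copy()
        Wm[flip] *= -1.0
        theta = 2 * b - fan_in
        return cls(
            meta=meta, W=Wm.reshape(W.shape), fan_in=fan_in, theta=theta, b=b,
            bn={"gamma": np.array(gamma), "beta": np.array(beta),
                "mean": np.array(mean), "var": np.array(var), "eps": eps,
                "W_orig": W.copy()},
        )


class ExportedSBCNN:
    """Integer-only SBCNN inference (the fully binarized pipeline).

    All arithmetic after input sampling is on small integers: +/-1 dot
    products compared to integer thresholds.  (Dot products are carried in
    float64 BLAS words, which is exact for these magnitudes.)
    """

    def __init__(self, stem, trunk, stats, dist, spec_json, num_classes):
        self.stem = stem
        self.trunk = trunk
        self.stats = stats
        self.dist = dist
        self.spec_json = spec_json
        self.num_classes = num_classes
        self.folded = True

    # -- layer application ----------------------------------------------
    @staticmethod
    def _apply(layer: ExportedLayer, x: np.ndarray, float_bn: bool = False) -> np.ndarray:
        kind = layer.meta["kind"]
        if kind == "pool":
            k = layer.meta["kernel"]
            B, C, H, W = x.shape
            return x.reshape(B, C, H // k, k, W // k, k).max(axis=(3, 5))
        if kind == "flatten":
            return x.reshape(x.shape[0], -1)
        if kind == "conv":
            cols, oh, ow = nn.im2col(
                x, layer.meta["kernel"], layer.meta["stride"], layer.meta["pad"], pad_value=-1.0
            )
            out_ch = layer.meta["out_ch"]
            Wm = (layer.bn["W_orig"] if float_bn and layer.bn else layer.W).reshape(out_ch, -1)
            B = x.shape[0]
            d = (Wm @ cols).reshape(out_ch, B, oh * ow).transpose(1, 0, 2).reshape(B, out_ch, oh, ow)
        else:  # fc
            Wm = layer.bn["W_orig"] if float_bn and layer.bn else layer.W
            d = x @ Wm.T
        if layer.theta is None:
            return d  # output layer: raw integer scores
        if float_bn:
            bn = layer.bn
            shape = (1, -1) + (1,) * (d.ndim - 2)
            z = bn["gamma"].reshape(shape) * (d - bn["mean"].reshape(shape)) / np.sqrt(
                bn["var"].reshape(shape) + bn["eps"]
            ) + bn["beta"].reshape(shape)
            return np.where(z >= 0, 1.0, -1.0)
        shape = (1, -1) + (1,) * (d.ndim - 2)
        return np.where(d >= layer.theta.reshape(shape), 1.0, -1.0)

    def _run(self, pm1: np.ndarray, n_pre: int, float_bn: bool) -> np.ndarray:
        x = pm1
        for layer in self.stem:
            x = self._apply(layer, x, float_bn)
        # aggregate presentations: sign of the per-pixel sum, ties to +1
        B = x.shape[0] // n_pre
        s = x.reshape(B, n_pre, *x.shape[1:]).sum(axis=1)
        x = np.where(s >= 0, 1.0, -1.0)
        for layer in self.trunk:
            x = self._apply(layer, x, float_bn)
        return x

    def sample_inputs(self, images, n_pre, rng):
        if self.dist == "uniform":
            x = rescale_minmax(images, self.stats)
        else:
            x = normalize(images, self.stats)
        bits = sample_presentations(x, n_pre, dist=self.dist, rng=rng)
        pm1 = bits.astype(np.float64) * 2.0 - 1.0
        pm1 = pm1.transpose(1, 0, 4, 2, 3)
        return np.ascontiguousarray(pm1.reshape(-1, *pm1.shape[2:]))

    def infer(
        self,
        images: np.ndarray,
        n_pre: int,
        rng: np.random.Generator,
        presentations: np.ndarray | None = None,
        float_reference: bool = False,
    ) -> np.ndarray:
        """Class scores (B, num_classes) as integers (pre-sign, for ranking)."""
        if n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if presentations is not None:
            pm1 = presentations
        else:
            images = np.asarray(images)
            if images.ndim == 3:
                images = images[None]
            pm1 = self.sample_inputs(images, n_pre, rng)
        scores = self._run(pm1, n_pre, float_bn=float_reference)
        return scores if float_reference else scores.astype(np.int64)

    def predict(self, images, n_pre, rng, batch_size: int = 64) -> np.ndarray:
        """Predicted labels, batched for memory."""
        images = np.asarray(images)
        out = []
        for i in range(0, images.shape[0], batch_size):
            s = self.infer(images[i : i + batch_size], n_pre, rng)
            out.append(np.argmax(s, axis=1))
        return np.concatenate(out)

    def scores(self, images, n_pre, rng, batch_size: int = 64) -> np.ndarray:
        images = np.asarray(images)
        out = []
        for i in range(0, images.shape[0], batch_size):
            out.append(self.infer(images[i : i + batch_size], n_pre, rng))
        return np.concatenate(out)


    # -- serialization ---------------------------------------------------
    # Container layout (.npz): "spec" holds a JSON header (network spec,
    # channel stats, sampling distribution, per-layer metadata); per
    # binarized layer i, "w{i}" holds the +/-1 weight matrix bit-packed
    # row-wise into little-endian uint64 words (bit 1 <-> +1, padding bits
    # zero) and "b{i}" the integer popcount thresholds.  The loader
    # validates fan-in and padding-mask consistency.

    def save(self, path) -> None:
        from .binary_core import BinaryTensor, save_model

        all_layers = list(self.stem) + list(self.trunk)
        header = {
            "spec": json.loads(self.spec_json),
            "stats": json.loads(self.stats.to_json()),
            "dist": self.dist,
            "num_classes": self.num_classes,
            "n_stem": len(self.stem),
            "layers": [l.meta for l in all_layers],
        }
        payload = []
        for layer in all_layers:
            # every layer carries a fanin entry so indices stay aligned
            entry: dict = {"fanin": np.array([layer.fan_in])}
            if layer.W is not None:
                Wm = layer.W.reshape(layer.W.shape[0], -1)
                entry["w"] = np.stack(
                    [BinaryTensor.from_signs(row).words for row in Wm]
                )
                if layer.b is not None:
                    entry["b"] = layer.b
            payload.append(entry)
        save_model(path, json.dumps(header), payload)

    @classmethod
    def load(cls, path) -> "ExportedSBCNN":
        from .binary_core import BinaryTensor, load_model

        header_json, payload = load_model(path)
        header = json.loads(header_json)
        metas = header["layers"]
        layers = []
        for meta, arrays in zip(metas, payload):
            if "w" in arrays:
                fan_in = int(arrays["fanin"][0])
                rows = []
                for words in arrays["w"]:
                    bt = BinaryTensor((fan_in,), words)  # validates padding mask
                    rows.append(bt.to_signs().astype(np.float64))
                W = np.stack(rows)
                if meta["kind"] == "conv":
                    expect = meta["in_ch"] * meta["kernel"] ** 2
                    shape = (meta["out_ch"], meta["in_ch"], meta["kernel"], meta["kernel"])
                else:
                    expect = meta["in_f"]
                    shape = (meta["out_f"], meta["in_f"])
                if fan_in != expect:
                    raise ValueError(
                        f"fan-in {fan_in} inconsistent with layer metadata {meta}"
                    )
                b = arrays.get("b")
                theta = 2 * b.astype(np.int64) - fan_in if b is not None else None
                layers.append(
                    ExportedLayer(meta=meta, W=W.reshape(shape), fan_in=fan_in, theta=theta, b=b)
                )
            else:
                layers.append(ExportedLayer(meta=meta, W=None, fan_in=0))
        n_stem = header["n_stem"]
        stats = ChannelStats.from_json(json.dumps(header["stats"]))
        return cls(
            stem=layers[:n_stem],
            trunk=layers[n_stem:],
            stats=stats,
            dist=header["dist"],
            spec_json=json.dumps(header["spec"]),
            num_classes=header["num_classes"],
        )


def aggregate_presentations(a_list) -> np.ndarray:
    """Elementwise sign of the sum of +/-1 presentation vectors (ties -> +1)."""
    if len(a_list) == 0:
        raise ValueError("need at least one presentation")
    s = np.sum([np.asarray(a) for a in a_list], axis=0)
    return np.where(s >= 0, 1, -1)


def sbcnn_infer(model, image, cfg: PresentationConfig, rng) -> np.ndarray:
    """Algorithm-1 inference on an exported (batch-norm-folded) model."""
    if not getattr(model, "folded", False):
        raise ValueError("model must be exported (batch norm folded) before inference; call .export()")
    return model.infer(image, cfg.n_infer, rng)[0]


# ----------------------------------------------------------------------
# Training


def train(
    model: SBCNN,
    dataset: ClassificationDataset,
    cfg: PresentationConfig,
    optimizer_cfg: dict | None = None,
) -> dict:
    """Binarization-aware training; returns a history dict.

    The stochastic input layer re-samples its bitstream (``cfg.n_train``
    presentations) on every forward pass, which acts as data augmentation.
    Raises on divergence (NaN loss) with epoch/batch diagnostics.
    """
    opt_cfg = {"lr": 5e-3, "epochs": 10, "batch_size": 32, "seed": 0}
    opt_cfg.update(optimizer_cfg or {})
    rng = np.random.default_rng(opt_cfg["seed"])
    opt = nn.Adam(model.params(), lr=opt_cfg["lr"])
    X, y = dataset.train_images, dataset.train_labels
    n = X.shape[0]
    history = {"loss": [], "train_accuracy": []}
    for epoch in range(opt_cfg["epochs"]):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, opt_cfg["batch_size"]):
            idx = order[start : start + opt_cfg["batch_size"]]
            scores = model.forward_scores(X[idx], cfg.n_train, rng, train=True)
            loss, dscores = nn.softmax_xent(scores, y[idx], scale=model.score_scale)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}, batch {start // opt_cfg['batch_size']}; "
                    "try a lower learning rate"
                )
            correct += int((np.argmax(scores, axis=1) == y[idx]).sum())
            opt.zero_grad()
            model.backward(dscores)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(correct / n)
    return history


# ----------------------------------------------------------------------
# Presentation-strategy experiment


def evaluate_strategies(
    model_factory,
    dataset: ClassificationDataset,
    n_grid,
    n_trials: int = 5,
    base_seed: int = 0,
    n_max: int = 256,
    optimizer_cfg: dict | None = None,
) -> pd.DataFrame:
    """Matched- vs max-presentations experiment.

    ``matched`` trains and infers at each n in ``n_grid``; ``max`` trains
    once per trial at ``n_max`` presentations and infers at each n.
    Returns a table with one row per (strategy, n): accuracy, mAP and ROC
    AUC, mean and std over ``n_trials`` trials.
    """
    from .evaluation import classification_metrics

    if len(n_grid) == 0:
        raise ValueError("n_grid must be non-empty")
    records = []
    for trial in range(n_trials):
        seed = base_seed + trial
        eval_rng = np.random.default_rng(10_000_019 + seed)

        def _fit(n_train: int):
            model = model_factory(seed)
            cfg = (
                PresentationConfig.matched(n_train)
                if n_train != n_max
                else PresentationConfig.max_presentations(n_infer=n_max, n_train=n_max)
            )
            opt = dict(optimizer_cfg or {})
            opt["seed"] = seed
            train(model, dataset, cfg, opt)
            return model.export()

        max_model = _fit(n_max)
        for n in n_grid:
            matched_model = max_model if n == n_max else _fit(n)
            for strategy, mdl in (("matched", matched_model), ("max", max_model)):
                scores = mdl.scores(dataset.test_images, n, eval_rng)
                m = classification_metrics(scores, dataset.test_labels)
                records.append({"trial": trial, "strategy": strategy, "n_pre": n, **m})
    df = pd.DataFrame.from_records(records)
    agg = (
        df.groupby(["strategy", "n_pre"])[["accuracy", "map", "roc_auc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    agg.columns = ["_".join(c).rstrip("_") for c in agg.columns]
    return agg
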