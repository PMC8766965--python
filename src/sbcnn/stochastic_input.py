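"""Stochastic binarization of multi-channel image inputs.

A stochastic binarized CNN (SBCNN) replaces the usual high-precision first
layer of a BNN with a stream of binary input samples.  Pixels are first
standardized per channel,

    X_r = (X_d - mu_i) / sigma_i,

then each presentation draws one bit per pixel by comparing the pixel to a
random threshold.  With the threshold drawn from the raw-domain normal
N(mu_i, sigma_i) — equivalently, comparing the normalized value to a
standard normal draw — the bit probability is Phi(X_r), the standard
normal CDF.  Averaging a stream of N_pre such bits gives an unbiased
estimate X_m of Phi(X_r) with variance Phi(1 - Phi)/N_pre.

A uniform-threshold baseline is also provided: pixels are min-max rescaled
to [0, 1] per channel over the training split, so the bit probability
equals the rescaled intensity.

The physical randomness source this emulates is the cycle-to-cycle
resistance variability of an oxide resistive memory (OxRAM) cell feeding a
voltage comparator; :func:`device_threshold_sequence` is a behavioural
model of that source (truncated-normal resistances mapped monotonically to
comparator thresholds), not a circuit simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import json

import numpy as np

__all__ = [
    "ChannelStats",
    "BitStream",
    "DeviceNoiseModel",
    "compute_channel_stats",
    "normalize",
    "denormalize",
    "rescale_minmax",
    "sample_bit",
    "sample_stream",
    "sample_presentations",
    "device_threshold_sequence",
]

Dist = Literal["normal", "uniform"]


@dataclass
class ChannelStats:
    """Per-channel pixel statistics computed on the training split.

    ``mu``/``sigma`` drive mean-sigma normalization (sigma > 0, population
    definition); ``vmin``/``vmax`` drive min-max rescaling for the uniform
    sampling baseline.
    """

    mu: np.ndarray
    sigma: np.ndarray
    vmin: np.ndarray | None = None
    vmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=np.float64))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0 for every channel")
        if self.vmin is not None:
            self.vmin = np.atleast_1d(np.asarray(self.vmin, dtype=np.float64))
        if self.vmax is not None:
            self.vmax = np.atleast_1d(np.asarray(self.vmax, dtype=np.float64))

    def to_json(self) -> str:
        d = {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}
        if self.vmin is not None:
            d["vmin"] = np.asarray(self.vmin).tolist()
            d["vmax"] = np.asarray(self.vmax).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ChannelStats":
        d = json.loads(s)
        return cls(
            mu=np.asarray(d["mu"]),
            sigma=np.asarray(d["sigma"]),
            vmin=np.asarray(d["vmin"]) if "vmin" in d else None,
            vmax=np.asarray(d["vmax"]) if "vmax" in d else None,
        )


@dataclass
class BitStream:
    """A length-``n_pre`` stream of {0,1} samples for one value."""

    bits: np.ndarray
    n_pre: int = field(init=False)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or self.bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D sequence")
        self.n_pre = self.bits.size

    @property
    def mean(self) -> float:
        """The averaged stream value X_m in [0, 1]."""
        return float(self.bits.mean())


@dataclass
class DeviceNoiseModel:
    """Behavioural model of an OxRAM-based stochastic threshold source.

    Cycle-to-cycle resistance follows a normal distribution truncated to
    positive values; a configurable monotone ``mapping`` converts sampled
    resistance (Ohm) to the comparator threshold (same units as the pixel
    domain it is used in).  Default mapping is the identity.
    """

    mu_R: float
    sigma_R: float
    mapping: Callable[[np.ndarray], np.ndarray] = field(default=lambda r: r)

    def __post_init__(self) -> None:
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")


def compute_channel_stats(images: np.ndarray, with_minmax: bool = True) -> ChannelStats:
    """Per-channel mean/std (population, ddof=0) over a stack of images.

    ``images`` has channels last: (..., H, W, C).  Raises if any channel is
    constant, instructing the caller to apply a floor value instead.
    """
    images = np.asarray(images, dtype=np.float64)
    flat = images.reshape(-1, images.shape[-1])
    if flat.shape[0] < 2:
        raise ValueError("need at least 2 pixels per channel")
    mu = flat.mean(axis=0)
    sigma = flat.std(axis=0)
    if np.any(sigma == 0):
        ch = int(np.argwhere(sigma == 0)[0][0])
        raise ValueError(
            f"channel {ch} is constant (sigma=0); supply a sigma floor (e.g. 1e-3) "
            "or add variability to the training images"
        )
    stats = ChannelStats(mu=mu, sigma=sigma)
    if with_minmax:
        stats.vmin = flat.min(axis=0)
        stats.vmax = flat.max(axis=0)
    return stats


def normalize(x_d: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Mean-sigma normalization X_r = (X_d - mu_i) / sigma_i (channels last)."""
    return (np.asarray(x_d, dtype=np.float64) - stats.mu) / stats.sigma


def denormalize(x_r: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    return np.asarray(x_r, dtype=np.float64) * stats.sigma + stats.mu


def rescale_minmax(x_d: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Min-max rescale raw pixels to [0, 1] per channel (uniform baseline)."""
    if stats.vmin is None or stats.vmax is None:
        raise ValueError("stats lack vmin/vmax; recompute with with_minmax=True")
    span = np.where(stats.vmax > stats.vmin, stats.vmax - stats.vmin, 1.0)
    return np.clip((np.asarray(x_d, dtype=np.float64) - stats.vmin) / span, 0.0, 1.0)


def sample_bit(
    x: np.ndarray | float,
    dist: Dist = "normal",
    rng: np.random.Generator | None = None,
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one binary sample per element by random-threshold comparison.

    For ``dist="normal"``, ``x`` is the normalized value X_r and the
    threshold is a standard normal draw, so P(bit=1) = Phi(x).  For
    ``dist="uniform"``, ``x`` is the min-max rescaled intensity in [0, 1]
    and the threshold is uniform on [0, 1], so P(bit=1) = x.

    ``thresholds`` overrides the threshold source (e.g. a
    :func:`device_threshold_sequence` output, broadcast against ``x``).
    """
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=np.float64)
    if thresholds is None:
        if dist == "normal":
            thresholds = rng.standard_normal(x.shape)
        elif dist == "uniform":
            thresholds = rng.uniform(0.0, 1.0, x.shape)
        else:
            raise ValueError(f"unknown dist {dist!r}")
    return (x > np.asarray(thresholds, dtype=np.float64)).astype(np.uint8)


def sample_stream(
    x: float,
    n_pre: int,
    dist: Dist = "normal",
    rng: np.random.Generator | None = None,
) -> BitStream:
    """Stream of ``n_pre`` independent binary presentations of one value."""
    if n_pre < 1:
        raise ValueError(f"n_pre must be >= 1, got {n_pre}")
    if rng is None:
        rng = np.random.default_rng()
    bits = sample_bit(np.full(n_pre, float(x)), dist=dist, rng=rng)
    return BitStream(bits)


def sample_presentations(
    x: np.ndarray,
    n_pre: int,
    dist: Dist = "normal",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized bitstreams for a whole tensor.

    Returns a uint8 array of shape ``(n_pre,) + x.shape``; axis 0 indexes
    the presentation.  ``x`` is in the domain required by ``dist`` (see
    :func:`sample_bit`).
    """
    if n_pre < 1:
        raise ValueError(f"n_pre must be >= 1, got {n_pre}")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=np.float64)
    return sample_bit(np.broadcast_to(x, (n_pre,) + x.shape), dist=dist, rng=rng)


def device_threshold_sequence(
    model: DeviceNoiseModel, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Comparator thresholds from the OxRAM variability model.

    Resistances are drawn from N(mu_R, sigma_R) truncated to > 0 (negative
    draws are rejected and redrawn) and mapped through ``model.mapping``.
    With an affine mapping and mu_R >> sigma_R this reproduces plain
    normal-threshold sampling.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    if model.sigma_R == 0:
        resist = np.full(n, float(model.mu_R))
        if model.mu_R <= 0:
            raise ValueError("mu_R must be > 0 when sigma_R == 0")
    else:
        resist = np.empty(n, dtype=np.float64)
        filled = 0
        while filled < n:
            draw = rng.normal(model.mu_R, model.sigma_R, size=n - filled)
            draw = draw[draw > 0]
            resist[filled : filled + draw.size] = draw
            filled += draw.size
    return np.asarray(model.mapping(resist), dtype=np.float64)
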