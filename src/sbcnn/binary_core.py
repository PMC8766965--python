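"""Bit-exact binarized tensor arithmetic.

A binarized neural network (BNN) constrains weights and activations to
{-1, +1}, so a multiply-accumulate collapses to an XNOR followed by a
population count: for bit-vectors ``w``, ``x`` of fan-in ``n``,

    popcount(XNOR(w, x)) = (n + w . x) / 2

and a neuron fires according to ``sign(popcount(XNOR(w, x)) - b)`` where
``b`` is a learned integer threshold in the popcount domain.

Conventions fixed here (and relied on by every other module):

* ``sign(0) = +1``.
* Bits are packed little-endian into 64-bit words: logical element
  ``64*j + i`` is bit ``i`` of word ``j``; logical ``+1`` is stored as
  bit 1, ``-1`` as bit 0.  Padding bits of the final word are stored as
  zero and masked out of every popcount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WORD_BITS = 64

__all__ = [
    "BinaryTensor",
    "NeuronThreshold",
    "binarize_sign",
    "xnor",
    "popcount",
    "binary_neuron",
    "ste_grad",
    "fold_batchnorm",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NeuronThreshold:
    """Popcount-domain threshold ``b`` of a binarized neuron with fan-in ``n``.

    ``b`` may lie outside [0, n] for a learned threshold (the neuron is then
    constant); ``n`` must be at least 1.
    """

    b: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"fan-in must be >= 1, got {self.n}")


class BinaryTensor:
    """A tensor with logical values in {-1, +1}, stored one bit per element.

    Parameters
    ----------
    shape
        Logical shape; the flat length is ``prod(shape)``.
    words
        Packed little-endian uint64 payload; padding bits must be zero.
    """

    __slots__ = ("shape", "words", "_nbits")

    def __init__(self, shape: tuple[int, ...], words: np.ndarray):
        self.shape = tuple(int(s) for s in shape)
        self._nbits = int(np.prod(self.shape)) if self.shape else 1
        expected = (self._nbits + WORD_BITS - 1) // WORD_BITS
        words = np.ascontiguousarray(words, dtype=np.uint64)
        if words.size != expected:
            raise ValueError(
                f"payload has {words.size} words, shape {self.shape} needs {expected}"
            )
        if int(np.bitwise_count(words & ~self.valid_mask(words.size)).sum()) != 0:
            raise ValueError("padding bits of the final word must be zero")
        self.words = words

    # -- construction ---------------------------------------------------
    @classmethod
    def from_signs(cls, values: np.ndarray) -> "BinaryTensor":
        """Pack a +/-1 (or boolean) array; values must be exactly -1/+1."""
        values = np.asarray(values)
        shape = values.shape
        if values.dtype == bool:
            bits = values.reshape(-1).astype(np.uint8)
        else:
            flat = values.reshape(-1)
            if not np.all(np.abs(flat) == 1):
                raise ValueError("values must be in {-1, +1}")
            bits = (flat > 0).astype(np.uint8)
        n = bits.size
        pad = (-n) % WORD_BITS
        if pad:
            bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
        words = np.packbits(bits, bitorder="little").view(np.uint64)
        return cls(shape, words)

    def valid_mask(self, n_words: int | None = None) -> np.ndarray:
        """Per-word mask of live bits (padding bits of the last word are 0)."""
        if n_words is None:
            n_words = self.words.size
        mask = np.full(n_words, np.uint64(0xFFFFFFFFFFFFFFFF), dtype=np.uint64)
        tail = self._nbits % WORD_BITS
        if tail:
            mask[-1] = np.uint64((1 << tail) - 1)
        return mask

    # -- accessors ------------------------------------------------------
    @property
    def nbits(self) -> int:
        """Number of live bits (== product of shape)."""
        return self._nbits

    def to_signs(self) -> np.ndarray:
        """Unpack to a +/-1 int8 array of the logical shape."""
        bits = np.unpackbits(self.words.view(np.uint8), bitorder="little")
        bits = bits[: self._nbits]
        return (bits.astype(np.int8) * 2 - 1).reshape(self.shape)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinaryTensor)
            and self.shape == other.shape
            and bool(np.array_equal(self.words, other.words))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryTensor(shape={self.shape}, nbits={self._nbits})"


def binarize_sign(x: np.ndarray) -> BinaryTensor:
    """Binarize a real tensor with ``sign``, mapping 0 to +1.

    Raises ``ValueError`` naming the first offending index if any element
    is NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    nan = np.isnan(x)
    if nan.any():
        idx = tuple(int(i) for i in np.argwhere(nan)[0])
        raise ValueError(f"NaN element at index {idx}")
    return BinaryTensor.from_signs(x >= 0)


def xnor(a: BinaryTensor, b: BinaryTensor) -> BinaryTensor:
    """Elementwise XNOR: output bit is +1 iff the inputs agree.

    Equivalent to the elementwise product in {-1, +1} arithmetic.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    words = ~(a.words ^ b.words) & a.valid_mask()
    return BinaryTensor(a.shape, words)


def popcount(a: BinaryTensor) -> int:
    """Number of +1 bits among the live bits (padding never counted)."""
    return int(np.bitwise_count(a.words).sum())


def binary_neuron(w: BinaryTensor, x: BinaryTensor, t: NeuronThreshold) -> int:
    """XNOR-popcount neuron: ``sign(popcount(XNOR(w, x)) - b)``.

    Algebraically equal to ``sign(w . x - (2b - n))`` since
    ``popcount(XNOR) = (n + w . x) / 2``.
    """
    if w.shape != x.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {x.shape}")
    if t.n != w.nbits:
        raise ValueError(f"fan-in mismatch: threshold n={t.n}, tensor has {w.nbits} bits")
    return 1 if popcount(xnor(w, x)) - t.b >= 0 else -1


def ste_grad(upstream: np.ndarray, pre_activation: np.ndarray) -> np.ndarray:
    """Straight-through estimator for the sign activation (hard-tanh window).

    The gradient passes unchanged where ``|pre_activation| <= 1`` and is
    zero elsewhere.
    """
    upstream = np.asarray(upstream)
    pre = np.asarray(pre_activation)
    if upstream.shape != pre.shape:
        raise ValueError(f"shape mismatch: {upstream.shape} vs {pre.shape}")
    return upstream * (np.abs(pre) <= 1.0)


def fold_batchnorm(
    gamma: np.ndarray,
    beta: np.ndarray,
    mean: np.ndarray,
    var: np.ndarray,
    n: int,
    eps: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold a batch-norm affine transform into integer popcount thresholds.

    The float inference path computes ``sign(gamma * (a - mean)/sqrt(var+eps)
    + beta)`` where ``a = w . x`` is the integer +/-1 dot product of fan-in
    ``n``.  For ``gamma > 0`` this fires iff ``a >= mean - beta*sigma/gamma``;
    in the popcount domain (``p = (n + a)/2``, integer) the exact equivalent
    is ``p >= ceil((n + theta)/2)``.  A negative ``gamma`` reverses the
    comparison; it is handled by negating the weight row (``flip`` output)
    so the stored comparison direction is uniform.

    Returns ``(b, flip)``: integer thresholds and a boolean per-channel
    weight-negation flag.  The fold is exact: integer inference with these
    thresholds matches the float path bit-for-bit, including sign(0) = +1
    ties.  Raises on a zero scale.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    mean = np.atleast_1d(np.asarray(mean, dtype=np.float64))
    var = np.atleast_1d(np.asarray(var, dtype=np.float64))
    if np.any(gamma == 0):
        raise ValueError("batch-norm scale must be non-zero to fold")
    sigma = np.sqrt(var + eps)
    theta = mean - beta * sigma / gamma  # fire iff a >= theta (gamma > 0)
    flip = gamma < 0
    # gamma < 0: fire iff a <= theta; negating weights maps a -> -a, so the
    # condition becomes a' >= -theta with the same >= comparison.
    theta = np.where(flip, -theta, theta)
    b = np.ceil((n + theta) / 2.0).astype(np.int64)
    return b, flip


# ----------------------------------------------------------------------
# Exported-model container
#
# Layout: a .npz archive with a JSON network-spec header under "spec" plus,
# per binarized layer i, "w{i}" (packed uint64 words of the +/-1 weight
# matrix, row-major, one row per output channel, each row padded to whole
# words) and "b{i}" (int64 popcount thresholds, one per output channel).
# The loader validates fan-in against the header and that padding bits of
# every row are zero.


def save_model(path, spec_json: str, layers: list[dict]) -> None:
    """Write an exported integer model.

    ``layers`` entries: {"w": BinaryTensor (out, fan_in) packed rows as a
    2-D uint64 array, "b": int64 thresholds or None, ...extra arrays}.
    """
    arrays: dict[str, np.ndarray] = {"spec": np.frombuffer(spec_json.encode(), dtype=np.uint8)}
    for i, layer in enumerate(layers):
        for key, val in layer.items():
            if val is not None:
                arrays[f"{key}{i}"] = np.asarray(val)
    np.savez(path, **arrays)


def load_model(path) -> tuple[str, list[dict]]:
    """Read an exported model; returns (spec JSON, per-layer array dicts)."""
    with np.load(path) as data:
        spec_json = bytes(data["spec"]).decode()
        keyed: dict[int, dict] = {}
        for key in data.files:
            if key == "spec":
                continue
            stem = key.rstrip("0123456789")
            idx = int(key[len(stem):])
            keyed.setdefault(idx, {})[stem] = data[key]
        layers = [keyed[i] for i in sorted(keyed)]
    return spec_json, layers
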