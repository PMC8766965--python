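"""Hardware cost estimation for binarized CNN inference on RRAM crossbars.

Accounts parameters and weight memory per precision (fp32 / int8 /
binary), counts operations per inference, maps weight matrices onto a
32 x 32 grid of 32 x 32 2T-2R bitcell tiles (block matrix multiplication,
one row computed per cycle), and converts operation counts into energy
through a configurable per-operation energy table.

Weight memory is reported in binary megabytes (MiB = 2^20 bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .sbcnn_model import NetworkSpec

__all__ = [
    "TileConfig",
    "EnergyTable",
    "CostReport",
    "count_params",
    "weight_memory",
    "memory_savings",
    "count_ops",
    "map_to_tiles",
    "energy",
    "cost_report",
]

_BYTES_PER_PARAM = {"fp32": 4, "int8": 1}
MIB = float(1 << 20)


@dataclass(frozen=True)
class TileConfig:
    """2T-2R crossbar geometry: a grid of tiles, row-sequential compute."""

    tile_rows: int = 32
    tile_cols: int = 32
    grid_rows: int = 32
    grid_cols: int = 32

    def __post_init__(self) -> None:
        if min(self.tile_rows, self.tile_cols, self.grid_rows, self.grid_cols) < 1:
            raise ValueError("all tile dimensions must be >= 1")

    @property
    def capacity(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass(frozen=True)
class EnergyTable:
    """Energy per operation, J/op.  Defaults are illustrative placeholders
    for relative comparisons; absolute energy claims require platform
    measurements supplied by the user."""

    e_xnor: float = 1e-14
    e_int8_mac: float = 1e-12
    e_fp32_mac: float = 2e-11
    e_sample: float = 5e-14

    def __post_init__(self) -> None:
        for name in ("e_xnor", "e_int8_mac", "e_fp32_mac", "e_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CostReport:
    """Memory / ops / latency / energy summary for one network."""

    per_layer_params: list
    total_params: int
    memory_mib: dict
    ops: dict
    cycles: int
    energy_uj: float


def count_params(spec: NetworkSpec) -> list[int]:
    """Weight-parameter count per layer.

    conv = out*in*k^2 (+out if bias); fc = out*in (+out if bias); pooling,
    activations, flatten and batch norm contribute zero (batch-norm affine
    parameters fold into integer thresholds at export and carry no weight
    memory).
    """
    counts = []
    for layer in spec.layers:
        if layer.kind == "conv":
            n = layer.out_ch * layer.in_ch * layer.kernel**2
            if layer.bias:
                n += layer.out_ch
        elif layer.kind == "fc":
            n = layer.out_f * layer.in_f
            if layer.bias:
                n += layer.out_f
        else:
            n = 0
        counts.append(n)
    return counts


def weight_memory(spec: NetworkSpec, precision: str) -> float:
    """Weight memory in MiB for a uniform precision.

    fp32 = 4 bytes/param, int8 = 1, binary = 1 bit/param with a per-layer
    ceil to whole bytes.
    """
    counts = count_params(spec)
    if precision in _BYTES_PER_PARAM:
        total = sum(counts) * _BYTES_PER_PARAM[precision]
    elif precision == "binary":
        total = sum(ceil(c / 8) for c in counts)
    else:
        raise ValueError(f"unknown precision {precision!r} (expected fp32|int8|binary)")
    return total / MIB


def memory_savings(
    spec_a: NetworkSpec,
    prec_a: str,
    spec_b: NetworkSpec,
    prec_b: str,
    rounded: bool = False,
) -> float:
    """Memory ratio weight_memory(a) / weight_memory(b)."""
    denom = weight_memory(spec_b, prec_b)
    if denom == 0:
        raise ValueError("denominator memory is zero")
    ratio = weight_memory(spec_a, prec_a) / denom
    return float(round(ratio)) if rounded else ratio


def count_ops(spec: NetworkSpec, n_pre: int = 1) -> dict:
    """Operations per inference, split into stochastic and binary parts.

    conv MACs = out_h*out_w*out_ch*in_ch*k^2, fc MACs = in*out.  The first
    (stochastic) conv layer runs once per presentation, so its MACs and
    one sampling op per input pixel are multiplied by ``n_pre``; every
    later binarized layer counts XNOR-accumulates 1:1 with MACs.
    """
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    shapes = spec.output_shapes()
    c, h, w = spec.input_shape
    first_ops = 0
    binary_ops = 0
    seen_first = False
    prev = (c, h, w)
    for layer, shape in zip(spec.layers, shapes):
        if layer.kind == "conv":
            oc, oh, ow = shape
            macs = oh * ow * oc * layer.in_ch * layer.kernel**2
            if not seen_first:
                first_ops = macs
                seen_first = True
            else:
                binary_ops += macs
        elif layer.kind == "fc":
            binary_ops += layer.in_f * layer.out_f
        prev = shape
    sampling_ops = c * h * w
    return {
        "first_layer_ops": first_ops * n_pre,
        "sampling_ops": sampling_ops * n_pre,
        "binary_ops": binary_ops,
        "total": first_ops * n_pre + sampling_ops * n_pre + binary_ops,
        "n_pre": n_pre,
    }


def map_to_tiles(dims: tuple[int, int], cfg: TileConfig | None = None) -> dict:
    """Map a weight matrix onto the tile grid.

    The matrix is partitioned into ceil(rows/32) * ceil(cols/32) blocks;
    blocks occupy distinct tiles up to the grid capacity (1024) and each
    resident block computes one row per cycle (32 cycles per pass); blocks
    beyond capacity serialize into additional 32-cycle passes.  One 5-bit
    look-up table per block is assumed for partial-sum reduction.
    """
    cfg = cfg or TileConfig()
    rows, cols = dims
    if rows < 1 or cols < 1:
        raise ValueError("matrix dims must be >= 1")
    blocks = ceil(rows / cfg.tile_rows) * ceil(cols / cfg.tile_cols)
    tiles_used = min(blocks, cfg.capacity)
    passes = ceil(blocks / cfg.capacity)
    cycles = passes * cfg.tile_rows
    return {
        "blocks": blocks,
        "tiles_used": tiles_used,
        "passes": passes,
        "cycles": cycles,
        "lookup_tables": blocks,
    }


def energy(ops_breakdown: dict, table: EnergyTable | None = None, first_layer_precision: str = "binary") -> float:
    """Total energy in microjoules: sum over op classes of count * J/op."""
    table = table or EnergyTable()
    per_mac = {
        "binary": table.e_xnor,
        "int8": table.e_int8_mac,
        "fp32": table.e_fp32_mac,
    }
    if first_layer_precision not in per_mac:
        raise ValueError(f"unknown precision {first_layer_precision!r}")
    joules = (
        ops_breakdown.get("first_layer_ops", 0) * per_mac[first_layer_precision]
        + ops_breakdown.get("sampling_ops", 0) * table.e_sample
        + ops_breakdown.get("binary_ops", 0) * table.e_xnor
    )
    return joules * 1e6


def cost_report(
    spec: NetworkSpec,
    precision: str = "binary",
    n_pre: int = 1,
    table: EnergyTable | None = None,
    cfg: TileConfig | None = None,
) -> CostReport:
    """Full cost summary: memory per precision, ops, cycles, energy."""
    counts = count_params(spec)
    ops = count_ops(spec, n_pre=n_pre)
    # total latency: cycles summed over conv/fc weight matrices
    cycles = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            cycles += map_to_tiles((layer.out_ch, layer.in_ch * layer.kernel**2), cfg)["cycles"]
        elif layer.kind == "fc":
            cycles += map_to_tiles((layer.out_f, layer.in_f), cfg)["cycles"]
    return CostReport(
        per_layer_params=counts,
        total_params=sum(counts),
        memory_mib={p: weight_memory(spec, p) for p in ("fp32", "int8", "binary")},
        ops=ops,
        cycles=cycles,
        energy_uj=energy(ops, table, first_layer_precision=precision if precision != "binary" else "binary"),
    )
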