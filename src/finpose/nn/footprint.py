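"""Theoretical minimum training-memory footprint accounting.

The accounting models a hypothetical minimal training implementation in which
every required buffer is allocated up front and never freed or repurposed,
individual operations use the smallest possible buffers (implicit padding for
depthwise convolutions, index-rearrangement layers recomputed in place rather
than materialized), and gradient accumulation is exploited to the fullest
extent that leaves results unchanged -- i.e. micro-batches of one sample
whenever no layer couples samples.  Batch normalization couples samples, so
with it the whole batch's activations must be held at once; the batch-size-
independent normalizations (instance, layer, group) permit micro-batch 1 and
hence a footprint independent of the effective batch size.

All scalars are 4-byte 32-bit floats.  The breakdown:

parameters / gradients / optimizer_state
    One float per parameter for weights and accumulated gradients; two for
    the AdamW first and second moments.
activations
    Every materialized intermediate tensor of one forward pass (stored once,
    as the backward pass consumes each exactly once), plus layer-private
    caches such as normalized activations, for one micro-batch.
io_buffers
    The input image and target heatmap buffers for one micro-batch.
workspace
    Two ping-pong buffers of the largest intermediate tensor for propagating
    activation gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .layers import Layer, Residual, Sequential
from .model import NetworkConfig, build_network, count_parameters

__all__ = ["FootprintReport", "theoretical_min_footprint", "activation_floats"]

BYTES_PER_FLOAT = 4


@dataclass
class FootprintReport:
    total_bytes: int
    breakdown: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.breakdown.values()):
            raise ValueError("footprint categories must be non-negative")
        if self.total_bytes != sum(self.breakdown.values()):
            raise ValueError("total must equal the sum of the breakdown")


def _walk(layer: Layer, in_shape: tuple[int, int, int]) -> tuple[tuple[int, int, int], int, int]:
    """Return (out_shape, per-sample activation floats, largest tensor floats)."""
    if isinstance(layer, Sequential):
        total = 0
        largest = 0
        shape = in_shape
        for child in layer.children:
            shape, floats, big = _walk(child, shape)
            total += floats
            largest = max(largest, big)
        return shape, total, largest
    if isinstance(layer, Residual):
        shape, floats, big = _walk(layer.body, in_shape)
        # The residual sum is one more materialized tensor.
        out_floats = shape[0] * shape[1] * shape[2]
        return shape, floats + out_floats, max(big, out_floats)
    out = layer.out_shape(in_shape)
    out_floats = out[0] * out[1] * out[2]
    floats = (out_floats if layer.materializes else 0) + layer.extra_cache_floats(in_shape)
    return out, floats, out_floats if layer.materializes else 0


def activation_floats(net, in_shape: tuple[int, int, int]) -> tuple[int, int]:
    """Per-sample (total activation floats, largest single tensor floats)."""
    in_floats = in_shape[0] * in_shape[1] * in_shape[2]
    _, total, largest = _walk(net, in_shape)
    return total, max(largest, in_floats)


def theoretical_min_footprint(
    cfg: NetworkConfig,
    batch: int = 16,
    effective_batch: int = 16,
) -> FootprintReport:
    """Minimum training footprint in bytes under the stated buffer rules.

    ``batch`` is the configured (micro-)batch size and ``effective_batch`` the
    batch size emulated through gradient accumulation; it must be a multiple
    of ``batch``.  Without batch normalization the accounting accumulates
    single-sample micro-batches, so the result is independent of both.
    """
    if effective_batch % batch:
        raise ValueError("effective_batch must be a multiple of batch")
    net = build_network(cfg)
    n_params = count_parameters(net)
    micro = batch if cfg.norm == "batch" else 1

    in_shape = (cfg.I, cfg.H, cfg.W)
    act_floats, largest = activation_floats(net, in_shape)
    o, ho, wo = cfg.output_shape

    breakdown = {
        "parameters": n_params * BYTES_PER_FLOAT,
        "gradients": n_params * BYTES_PER_FLOAT,
        "optimizer_state": 2 * n_params * BYTES_PER_FLOAT,
        "activations": act_floats * micro * BYTES_PER_FLOAT,
        "io_buffers": (cfg.I * cfg.H * cfg.W + o * ho * wo) * micro * BYTES_PER_FLOAT,
        "workspace": 2 * largest * micro * BYTES_PER_FLOAT,
    }
    return FootprintReport(total_bytes=sum(breakdown.values()), breakdown=breakdown)
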