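"""Pose-network architectures: isotropic and hierarchical heatmap regressors.

Both macro-architectures map a single-channel image (B, I, H, W) to per-
keypoint heatmaps (B, O, H/2, W/2).

Isotropic
    An 8x8 pixel-unshuffle patchifies the image; all N residual blocks then
    run at the constant internal resolution (H/8, W/8) with M channels; the
    outro expands channels 2x, applies hard swish and spatial dropout, maps to
    (patch/2)^2 * O channels and pixel-shuffles up to H/2.

Hierarchical
    A classic encoder-decoder: a 4x4 stride-2 intro plus two stride-2
    downsampling stages reach (H/8, W/8) where all N residual blocks run with
    M channels (channel width halves per 2x increase in resolution); two
    transposed-conv upsampling stages return to H/2, where a lightweight
    outro maps to O channels.  No encoder-decoder skip connections.

The residual block is a MobileNetV3 inverted bottleneck (expand 1x1 ->
depthwise -> squeeze-excitation -> project 1x1), either in its full form
("mnv3": normalization and activation after expand and depthwise, and
normalization after project) or the slimmed variant ("slim") that keeps
exactly one normalization and one activation; which ones are kept is
configurable, defaulting to the normalization after the depthwise convolution
and the hard swish after the expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .layers import (
    Conv2d,
    ConvTranspose2d,
    HardSwish,
    Layer,
    Normalization,
    PixelShuffle,
    PixelUnshuffle,
    Residual,
    Sequential,
    SpatialDropout,
    SqueezeExcite,
    DEFAULT_DTYPE,
)

__all__ = [
    "NetworkConfig",
    "Network",
    "build_network",
    "count_parameters",
    "TOUCH_PRESET",
    "VISUOMOTOR_PRESET",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class NetworkConfig:
    """All architecture hyperparameters.

    H, W, I, M, O, N are the input height/width, input channels, middle
    channels, output channels (= number of keypoints), and residual-block
    count; E is the in-block channel expansion ratio.  ``variant`` selects the
    full MobileNetV3 block ("mnv3") or the slimmed block ("slim");
    ``slim_norm`` / ``slim_act`` choose which normalization ("expand",
    "depthwise", "project") and which activation ("expand", "depthwise") the
    slim block keeps, so all six keep-combinations remain constructible.
    """

    H: int = 256
    W: int = 256
    I: int = 1
    M: int = 16
    O: int = 1
    N: int = 10
    E: int = 2
    patch: int = 8
    kernel: int = 3
    norm: str = "instance"
    variant: str = "slim"
    macro: str = "isotropic"
    drop_prob: float = 0.05
    norm_eps: float = 1e-3
    bn_momentum: float = 0.9
    norm_groups: int = 8
    slim_norm: str = "depthwise"
    slim_act: str = "expand"

    def __post_init__(self) -> None:
        if self.patch % 2 or self.patch < 2:
            raise ValueError("patch size must be even and >= 2")
        if self.H % self.patch or self.W % self.patch:
            raise ValueError(f"H, W must be divisible by the patch size {self.patch}")
        if self.macro == "hierarchical" and (self.H % 8 or self.W % 8 or self.M % 4):
            raise ValueError("hierarchical macro requires H, W divisible by 8 and M by 4")
        if self.norm not in Normalization.KINDS:
            raise ValueError(f"norm must be one of {Normalization.KINDS}")
        if self.variant not in ("mnv3", "slim"):
            raise ValueError("variant must be 'mnv3' or 'slim'")
        if self.macro not in ("isotropic", "hierarchical"):
            raise ValueError("macro must be 'isotropic' or 'hierarchical'")
        if self.kernel not in (3, 5, 7):
            raise ValueError("depthwise kernel must be 3, 5, or 7")
        if self.slim_norm not in ("expand", "depthwise", "project"):
            raise ValueError("slim_norm must be 'expand', 'depthwise', or 'project'")
        if self.slim_act not in ("expand", "depthwise"):
            raise ValueError("slim_act must be 'expand' or 'depthwise'")
        if not 1 <= self.O <= 10:
            raise ValueError("O (keypoints) must be in [1, 10]")

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return (self.O, self.H // 2, self.W // 2)


#: Single-well escape-response recordings: 512x512 crops, 7 keypoints.
TOUCH_PRESET = NetworkConfig(H=512, W=512, I=1, M=32, O=7, N=10)

#: Multiwell visuomotor recordings: 256x256 ROI crops, 1 keypoint.
VISUOMOTOR_PRESET = NetworkConfig(H=256, W=256, I=1, M=16, O=1, N=10)


class Network(Sequential):
    """A built pose network; a Sequential with its config attached."""

    def __init__(self, cfg: NetworkConfig, *layers: Layer):
        super().__init__(*layers)
        self.cfg = cfg

    def __call__(self, x, *, training=False, rng=None):
        return self.forward(x, training=training, rng=rng)


def _norm(cfg: NetworkConfig, channels: int, dtype) -> Normalization:
    return Normalization(
        channels,
        kind=cfg.norm,
        eps=cfg.norm_eps,
        momentum=cfg.bn_momentum,
        groups=cfg.norm_groups,
        dtype=dtype,
    )


def _residual_block(cfg: NetworkConfig, channels: int, dtype) -> Residual:
    """One inverted-bottleneck residual block at ``channels`` width."""
    mid = cfg.E * channels
    body: list[Layer] = []
    if cfg.variant == "mnv3":
        keep_norm = {"expand", "depthwise", "project"}
        keep_act = {"expand", "depthwise"}
    else:
        keep_norm = {cfg.slim_norm}
        keep_act = {cfg.slim_act}

    # Expansion 1x1.  Gain sqrt(2) when a nonlinearity (directly or after a
    # normalization) follows, else 1.
    expand_gain = SQRT2 if "expand" in keep_act else 1.0
    body.append(Conv2d(channels, mid, 1, init_gain=expand_gain, dtype=dtype))
    if "expand" in keep_norm:
        body.append(_norm(cfg, mid, dtype))
    if "expand" in keep_act:
        body.append(HardSwish())

    dw_gain = SQRT2 if "depthwise" in keep_act else 1.0
    body.append(
        Conv2d(
            mid,
            mid,
            cfg.kernel,
            padding=cfg.kernel // 2,
            depthwise=True,
            init_gain=dw_gain,
            dtype=dtype,
        )
    )
    if "depthwise" in keep_norm:
        body.append(_norm(cfg, mid, dtype))
    if "depthwise" in keep_act:
        body.append(HardSwish())

    body.append(SqueezeExcite(mid, dtype=dtype))

    # Projection 1x1: the last convolution of the block.  Its init gain is
    # scaled by 1/sqrt(N) so the residual stream's variance stays bounded.
    project = Conv2d(mid, channels, 1, init_gain=1.0 / math.sqrt(cfg.N), dtype=dtype)
    project.residual_last = True
    body.append(project)
    if "project" in keep_norm:
        body.append(_norm(cfg, channels, dtype))

    return Residual(Sequential(*body))


def _build_isotropic(cfg: NetworkConfig, dtype) -> Network:
    layers: list[Layer] = [
        PixelUnshuffle(cfg.patch),
        Conv2d(cfg.I * cfg.patch**2, cfg.M, 1, init_gain=1.0, dtype=dtype),
        _norm(cfg, cfg.M, dtype),
    ]
    for _ in range(cfg.N):
        layers.append(_residual_block(cfg, cfg.M, dtype))
    shuffle = cfg.patch // 2
    final = Conv2d(2 * cfg.M, shuffle**2 * cfg.O, 1, init_zero=True, dtype=dtype)
    final.network_final = True
    layers += [
        Conv2d(cfg.M, 2 * cfg.M, 1, init_gain=SQRT2, dtype=dtype),
        HardSwish(),
        SpatialDropout(cfg.drop_prob),
        final,
        PixelShuffle(shuffle),
    ]
    return Network(cfg, *layers)


def _build_hierarchical(cfg: NetworkConfig, dtype) -> Network:
    c2, c4, c8 = cfg.M // 4, cfg.M // 2, cfg.M  # widths at H/2, H/4, H/8
    layers: list[Layer] = [
        Conv2d(cfg.I, c2, 4, stride=2, padding=1, init_gain=1.0, dtype=dtype),
        _norm(cfg, c2, dtype),
        Conv2d(c2, c4, 2, stride=2, init_gain=1.0, dtype=dtype),
        _norm(cfg, c4, dtype),
        Conv2d(c4, c8, 2, stride=2, init_gain=1.0, dtype=dtype),
        _norm(cfg, c8, dtype),
    ]
    for _ in range(cfg.N):
        layers.append(_residual_block(cfg, c8, dtype))
    final = Conv2d(c4, cfg.O, 1, init_zero=True, dtype=dtype)
    final.network_final = True
    layers += [
        ConvTranspose2d(c8, c4, 2, init_gain=1.0, dtype=dtype),
        _norm(cfg, c4, dtype),
        ConvTranspose2d(c4, c2, 2, init_gain=1.0, dtype=dtype),
        _norm(cfg, c2, dtype),
        Conv2d(c2, c4, 1, init_gain=SQRT2, dtype=dtype),
        HardSwish(),
        SpatialDropout(cfg.drop_prob),
        final,
    ]
    return Network(cfg, *layers)


def build_network(cfg: NetworkConfig, dtype=DEFAULT_DTYPE) -> Network:
    """Build (but do not initialize) the configured network.

    Weights start at zero; call :func:`finpose.training.init_weights` for the
    documented initialization scheme.
    """
    if cfg.macro == "isotropic":
        return _build_isotropic(cfg, dtype)
    return _build_hierarchical(cfg, dtype)


def count_parameters(net_or_cfg) -> int:
    """Exact number of trainable scalars of a network or config."""
    net = build_network(net_or_cfg) if isinstance(net_or_cfg, NetworkConfig) else net_or_cfg
    return int(sum(p.value.size for p in net.parameters()))
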