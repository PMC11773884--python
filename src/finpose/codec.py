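"""Conversion between keypoint coordinates and per-keypoint Gaussian heatmaps.

The pose network regresses, for each of up to 10 body keypoints, a 2D Gaussian
"probability" map at half the input resolution instead of raw coordinates.
This module owns both directions of that encoding plus the accuracy metrics
used to score predictions (percentage of correct keypoints within a pixel
radius, and the relative accuracy of data-ablated models).

Coordinate conventions
----------------------
Pixels are indexed 0-based with x rightward and y downward; coordinates refer
to pixel centers.  With the fixed 2x downscale between input and heatmap, the
heatmap pixel ``j`` covers input pixels ``2j`` and ``2j + 1``, so an input
coordinate ``x`` maps to heatmap coordinate ``x / 2 - 0.25`` and back via
``2 * hx + 0.5``.  This keeps the encode/decode round trip unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Keypoints",
    "HeatmapStack",
    "CodecConfig",
    "HEATMAP_SCALE",
    "encode_targets",
    "decode_heatmaps",
    "pck",
    "relative_accuracy",
]

#: Fixed ratio of input resolution to heatmap resolution.
HEATMAP_SCALE = 2

MAX_KEYPOINTS = 10


@dataclass
class Keypoints:
    """Ordered keypoint coordinates for one frame, in input-image pixels.

    ``coords`` has shape (K, 2) with columns (x, y); ``confidence`` optionally
    carries the decoded heatmap peak value per keypoint (NaN-free, in [0, 1]
    for encoded targets; unbounded for raw network output).
    """

    coords: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must have shape (K, 2), got {self.coords.shape}")
        k = self.coords.shape[0]
        if not 1 <= k <= MAX_KEYPOINTS:
            raise ValueError(f"number of keypoints must be in [1, {MAX_KEYPOINTS}], got {k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("keypoint coordinates must be finite")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (k,):
                raise ValueError("confidence must have shape (K,)")

    @property
    def n_keypoints(self) -> int:
        return self.coords.shape[0]


@dataclass
class HeatmapStack:
    """K real-valued heatmaps of shape (K, H/2, W/2) at the output resolution."""

    values: np.ndarray
    scale: int = HEATMAP_SCALE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("heatmap values must have shape (K, h, w)")

    @property
    def n_keypoints(self) -> int:
        return self.values.shape[0]


@dataclass
class CodecConfig:
    """Tunables of the target encoding.

    sigma
        SD of the target Gaussian in *heatmap* pixels.  Default 2: small
        enough to resolve keypoints to ~1.5 input px, large enough for a
        smooth regression target.
    wiggle_sd
        SD of the random jitter ("wiggle") applied to the keypoint coordinate
        (in *input* pixels) before encoding a training target.  The image is
        untouched; only the Gaussian center moves.
    correctness_radius
        Radius (input pixels) within which a prediction counts as correct for
        the PCK metric.  3 px suits high-magnification single-well recordings;
        1.5 px suits multiwell recordings where larvae span fewer pixels.
    """

    sigma: float = 2.0
    wiggle_sd: float = 0.25
    correctness_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.wiggle_sd < 0:
            raise ValueError("wiggle_sd must be >= 0")
        if self.correctness_radius <= 0:
            raise ValueError("correctness_radius must be > 0")


def input_to_heatmap(coords: np.ndarray, scale: int = HEATMAP_SCALE) -> np.ndarray:
    """Map input-pixel coordinates to heatmap-pixel coordinates."""
    coords = np.asarray(coords, dtype=float)
    return coords / scale - (scale - 1) / (2 * scale)


def heatmap_to_input(coords: np.ndarray, scale: int = HEATMAP_SCALE) -> np.ndarray:
    """Map heatmap-pixel coordinates back to input-pixel coordinates."""
    coords = np.asarray(coords, dtype=float)
    return coords * scale + (scale - 1) / 2


def encode_targets(
    kp: Keypoints,
    heatmap_shape: tuple[int, int],
    cfg: CodecConfig | None = None,
    rng: np.random.Generator | None = None,
) -> HeatmapStack:
    """Encode keypoints as per-channel 2D Gaussians with peak value 1.

    Channel k holds ``exp(-d^2 / (2 sigma^2))`` where d is the distance (in
    heatmap pixels) to keypoint k mapped into heatmap coordinates.  When an
    ``rng`` is given and ``wiggle_sd > 0``, isotropic Gaussian jitter is first
    added to the coordinates (in input pixels) as label-noise augmentation.
    """
    cfg = cfg or CodecConfig()
    h, w = heatmap_shape
    coords = kp.coords.copy()
    if rng is not None and cfg.wiggle_sd > 0:
        coords = coords + rng.normal(0.0, cfg.wiggle_sd, size=coords.shape)
    centers = input_to_heatmap(coords)
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    maps = np.empty((kp.n_keypoints, h, w), dtype=float)
    for k, (cx, cy) in enumerate(centers):
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        maps[k] = np.exp(-d2 / (2.0 * cfg.sigma**2))
    return HeatmapStack(maps)


def _parabolic_offset(wm: float, w0: float, wp: float) -> float:
    """Subpixel offset of a peak from log-quadratic interpolation.

    For samples of a Gaussian this is exact: the log of the three values
    around the peak is a parabola whose vertex sits at the true center.
    Falls back to a plain intensity-weighted centroid when a neighbor is
    non-positive (where the log is undefined).
    """
    if wm <= 0.0 or wp <= 0.0:
        total = max(wm, 0.0) + w0 + max(wp, 0.0)
        return (max(wp, 0.0) - max(wm, 0.0)) / total if total > 0 else 0.0
    lm, l0, lp = np.log(wm), np.log(w0), np.log(wp)
    denom = lm - 2.0 * l0 + lp
    if denom >= 0.0:  # flat or non-concave: no refinement
        return 0.0
    return float(np.clip(0.5 * (lm - lp) / denom, -1.0, 1.0))


def decode_heatmaps(hm: HeatmapStack) -> Keypoints:
    """Decode each channel to a subpixel keypoint location plus confidence.

    The global maximum of each channel is refined per axis by log-parabolic
    interpolation over its immediate neighbors -- exact for Gaussian-shaped
    peaks, unlike an intensity-weighted centroid, which shrinks toward the
    window center -- and mapped back to input pixels.  Confidence is the raw
    peak value.  An all-zero channel is flagged undetected: confidence 0,
    coordinates at the argmax (0, 0).  Ties between equal maxima resolve to
    the lowest row-major index; peaks on the border are not refined along the
    clipped axis.
    """
    values = np.asarray(hm.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("heatmap values must be finite")
    k, h, w = values.shape
    coords = np.zeros((k, 2), dtype=float)
    conf = np.zeros(k, dtype=float)
    for i in range(k):
        chan = values[i]
        flat = int(np.argmax(chan))  # lowest row-major index on ties
        py, px = divmod(flat, w)
        peak = chan[py, px]
        conf[i] = peak
        cx, cy = float(px), float(py)
        if peak > 0.0:
            if 0 < px < w - 1:
                cx += _parabolic_offset(chan[py, px - 1], peak, chan[py, px + 1])
            if 0 < py < h - 1:
                cy += _parabolic_offset(chan[py - 1, px], peak, chan[py + 1, px])
        coords[i] = heatmap_to_input(np.array([cx, cy]))
    return Keypoints(coords, conf)


def _stack_coords(seq) -> np.ndarray:
    arrs = []
    for item in seq:
        arrs.append(item.coords if isinstance(item, Keypoints) else np.asarray(item, float))
    return np.stack(arrs, axis=0)


def pck(pred, truth, radius: float) -> float:
    """Fraction of keypoints predicted strictly within ``radius`` input px.

    ``pred`` and ``truth`` are matched sequences of :class:`Keypoints` (or
    (K, 2) arrays).  Errors are Euclidean; the boundary uses strict ``<``.
    """
    p = _stack_coords(pred)
    t = _stack_coords(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction/truth shape mismatch: {p.shape} vs {t.shape}")
    err = np.linalg.norm(p - t, axis=-1)
    return float(np.mean(err < radius))


def count_correct(pred, truth, radius: float) -> int:
    """Number of keypoints predicted strictly within ``radius`` input px."""
    p = _stack_coords(pred)
    t = _stack_coords(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction/truth shape mismatch: {p.shape} vs {t.shape}")
    err = np.linalg.norm(p - t, axis=-1)
    return int(np.sum(err < radius))


def relative_accuracy(correct_ablated: int, correct_full: int) -> float:
    """Correct-keypoint count of an ablated-data model over the full-data count."""
    if correct_full <= 0:
        raise ValueError("correct_full must be > 0 for relative accuracy")
    return correct_ablated / correct_full
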