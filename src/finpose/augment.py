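"""Label-consistent on-the-fly augmentation and dataset standardization.

The training pipeline randomly divides a labeled dataset into training (75%)
and validation (25%) splits, standardizes all images with the mean and SD
pooled over the *training* split only, and augments training images on the
fly: random gamma and brightness (photometric), then random resize, flips,
rotation, and pad/crop translation (geometric, composed into a single affine
transform applied once, with keypoints mapped through the exact same affine),
then standardization, then additive Gaussian noise.  Validation images are
only standardized.

Augmentation magnitudes default to: gamma exponent log-uniform in
[0.75, 1.33], brightness +-0.1, resize +-10%, rotation uniform over the full
circle (fish orientation in a well is unconstrained), translation up to +-5%
of the side, flips with probability 0.5 per axis, and post-standardization
noise SD 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import affine_transform

from .codec import Keypoints
from .synthetic import LabeledFrame, PoseDataset

__all__ = [
    "AugmentConfig",
    "SplitStats",
    "split_dataset",
    "compute_split_stats",
    "standardize",
    "augment_pair",
]


@dataclass
class AugmentConfig:
    gamma_range: tuple[float, float] = (0.75, 1.33)
    brightness_range: float = 0.1
    resize_range: float = 0.10
    rotate_range: float = 360.0
    pad_crop_max: float = 0.05
    flip_prob: float = 0.5
    noise_sd: float = 0.05
    enabled: bool = True
    max_retries: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.gamma_range
        if not lo <= 1.0 <= hi or lo <= 0:
            raise ValueError("gamma_range must contain the identity exponent 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        for name in ("brightness_range", "resize_range", "pad_crop_max", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """A config whose every draw is the identity transform (no noise)."""
        return cls(
            gamma_range=(1.0, 1.0),
            brightness_range=0.0,
            resize_range=0.0,
            rotate_range=0.0,
            pad_crop_max=0.0,
            flip_prob=0.0,
            noise_sd=0.0,
        )


@dataclass
class SplitStats:
    """Pixel-intensity mean and SD pooled over the training split."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def split_dataset(
    ds: PoseDataset, train_fraction: float = 0.75, seed: int = 0
) -> tuple[PoseDataset, PoseDataset]:
    """Seeded random partition into disjoint, exhaustive train/val datasets.

    The training split gets ``round(n * train_fraction)`` frames; the
    validation split the remainder.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ds)
    if n == 0:
        raise ValueError("dataset is empty")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    order = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # both splits nonempty
    train_idx, val_idx = order[:n_train], order[n_train:]
    make = lambda idx: PoseDataset(
        frames=[ds.frames[i] for i in idx],
        n_keypoints=ds.n_keypoints,
        frame_size=ds.frame_size,
        seed=ds.seed,
    )
    return make(train_idx), make(val_idx)


def compute_split_stats(train: PoseDataset) -> SplitStats:
    """Pixelwise-pooled mean and SD over all training images."""
    if len(train) == 0:
        raise ValueError("training split is empty")
    stack = train.images()
    mean = float(stack.mean())
    sd = float(stack.std())
    if sd == 0.0:
        raise ValueError("training images are constant; cannot standardize")
    return SplitStats(mean=mean, sd=sd)


def standardize(image: np.ndarray, stats: SplitStats) -> np.ndarray:
    return (image - stats.mean) / stats.sd


def _affine_params(cfg: AugmentConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one random geometric transform; return (2x2 matrix A, translation t).

    A point p maps to ``A @ (p - c) + c + t`` with c the image center.
    """
    lo, hi = 1.0 - cfg.resize_range, 1.0 + cfg.resize_range
    scale = rng.uniform(lo, hi)
    theta = math.radians(rng.uniform(-cfg.rotate_range / 2, cfg.rotate_range / 2))
    flip_x = -1.0 if rng.random() < cfg.flip_prob else 1.0
    flip_y = -1.0 if rng.random() < cfg.flip_prob else 1.0
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    a = rot @ np.diag([scale * flip_x, scale * flip_y])
    return a, None  # translation drawn later (needs the side length)


def augment_pair(
    frame: LabeledFrame,
    cfg: AugmentConfig,
    stats: SplitStats,
    rng: np.random.Generator,
) -> LabeledFrame:
    """One random augmentation of an image/keypoints pair.

    Order: photometric (gamma, brightness; keypoints untouched) -> one
    composed affine (resize, flips, rotation, translation; keypoints mapped
    exactly) -> standardization -> Gaussian noise.  If a drawn affine pushes
    every keypoint outside the frame it is resampled (bounded retries).
    Output size equals input size; out-of-view regions are filled with the
    image median (the background level estimate).
    """
    img = np.asarray(frame.image, dtype=float)
    h, w = img.shape
    kp = frame.keypoints.coords

    if cfg.enabled:
        gamma = math.exp(rng.uniform(math.log(cfg.gamma_range[0]), math.log(cfg.gamma_range[1])))
        brightness = rng.uniform(-cfg.brightness_range, cfg.brightness_range)
        img = np.clip(np.clip(img, 0.0, 1.0) ** gamma + brightness, 0.0, 1.0)

        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        fill = float(np.median(img))
        for attempt in range(cfg.max_retries + 1):
            a, _ = _affine_params(cfg, rng)
            t = rng.uniform(
                -cfg.pad_crop_max, cfg.pad_crop_max, size=2
            ) * np.array([w, h])
            new_kp = (kp - center) @ a.T + center + t
            inside = (
                (new_kp[:, 0] >= 0)
                & (new_kp[:, 0] <= w - 1)
                & (new_kp[:, 1] >= 0)
                & (new_kp[:, 1] <= h - 1)
            )
            if inside.any():
                break
        else:
            raise RuntimeError(
                f"no valid augmentation after {cfg.max_retries} retries "
                "(all keypoints pushed outside the frame)"
            )
        # scipy's affine_transform maps *output* coordinates to input
        # coordinates (row-column order), so pass the inverse transform.
        a_inv = np.linalg.inv(a)
        a_inv_rc = a_inv[::-1, ::-1]  # xy -> row-col convention
        center_rc = center[::-1]
        t_rc = t[::-1]
        offset = center_rc - a_inv_rc @ (center_rc + t_rc)
        img = affine_transform(
            img, a_inv_rc, offset=offset, order=1, mode="constant", cval=fill
        )
        kp = new_kp

    img = standardize(img, stats)
    if cfg.enabled and cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return LabeledFrame(image=img, keypoints=Keypoints(kp), pose=frame.pose, scene=frame.scene)
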