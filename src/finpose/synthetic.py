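"""Seeded generator of synthetic larval-zebrafish frames and movies.

Real behavioral recordings show a dark, curved, tapered larva on a bright
well background, optionally with well edges, a touch probe entering the field
of view, uneven illumination, defocus, and sensor noise.  This module renders
a cheap geometric emulation of that appearance -- a chain of soft-edged
filled circles along a constant-curvature arc with linear taper, Gaussian
blurred -- together with exact ground-truth keypoints on the body midline, so
that the codec, augmentation, network, training, and kinematics modules can
all be exercised and validated without any recorded data.

Everything is a pure function of its inputs and a seed: one root seed is
split per-frame through ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .codec import Keypoints
from .kinematics import TrajectorySeries

__all__ = [
    "PoseParams",
    "SceneSpec",
    "SceneRanges",
    "TrajectoryScript",
    "LabeledFrame",
    "PoseDataset",
    "PoseOutsideFrameError",
    "render_frame",
    "generate_dataset",
    "generate_trajectory_movie",
    "midline_points",
    "keypoint_arc_fractions",
]

#: Default head-to-tail half-width taper, as fractions of body length.
#: Head is a rounded bulb (~9% of body length in half-width) tapering to a
#: thin tail tip, roughly matching a 2-7 dpf larva seen from above.
DEFAULT_WIDTH_PROFILE = (0.090, 0.085, 0.060, 0.040, 0.027, 0.016, 0.008)

#: Arc-length fraction of the single-keypoint label (between the two eyes,
#: slightly caudal of the rostral tip).
SINGLE_KEYPOINT_FRACTION = 0.10


class PoseOutsideFrameError(ValueError):
    """Raised when a requested pose does not fit inside the frame."""


@dataclass
class PoseParams:
    """Geometry of one rendered fish.

    centroid
        (x, y) center of mass of the midline, pixels.
    heading
        Direction of the mean body axis in degrees (0 = +x, counterclockwise
        positive in image coordinates with y down).
    arc_curvature
        Total turning of the body midline in degrees, signed; 0 is straight.
    body_length
        Arc length of the midline in pixels.
    body_width_profile
        Half-width taper fractions of body length, head to tail.
    """

    centroid: tuple[float, float]
    heading: float = 0.0
    arc_curvature: float = 0.0
    body_length: float = 30.0
    body_width_profile: tuple[float, ...] = DEFAULT_WIDTH_PROFILE

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be > 0")
        if not abs(self.arc_curvature) < 360:
            raise ValueError("|arc_curvature| must be < 360 degrees")


@dataclass
class SceneSpec:
    """Rendering conditions of one frame.

    Intensity levels are fractions of full scale in [0, 1]; the background is
    bright and the fish dark.  ``well_edge`` is an optional dark circle
    outline ((cx, cy), radius, darkness); ``probe`` an optional dark bar
    occluder ((x, y) tip, angle degrees, half-width px) entering from the
    frame border; ``illumination_gradient`` a corner-to-corner linear
    intensity slope (fraction of full scale); ``noise_sd`` the SD of additive
    Gaussian sensor noise; ``blur_sigma`` the defocus blur in pixels.
    """

    frame_size: tuple[int, int] = (256, 256)
    background_level: float = 0.85
    fish_level: float = 0.25
    well_edge: tuple[tuple[float, float], float, float] | None = None
    probe: tuple[tuple[float, float], float, float] | None = None
    illumination_gradient: float = 0.0
    noise_sd: float = 0.01
    blur_sigma: float = 0.8

    def __post_init__(self) -> None:
        for name in ("background_level", "fish_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass
class LabeledFrame:
    """One grayscale image in [0, 1] plus its ground-truth keypoints."""

    image: np.ndarray
    keypoints: Keypoints
    pose: PoseParams | None = None
    scene: SceneSpec | None = None


@dataclass
class PoseDataset:
    """A labeled pose dataset: frames plus generation provenance."""

    frames: list[LabeledFrame]
    n_keypoints: int
    frame_size: tuple[int, int]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def images(self) -> np.ndarray:
        return np.stack([f.image for f in self.frames])

    def coords(self) -> np.ndarray:
        return np.stack([f.keypoints.coords for f in self.frames])


@dataclass
class SceneRanges:
    """Uniform sampling ranges for randomized dataset generation.

    ``well_prob`` and ``probe_prob`` are the per-frame probabilities of adding
    a well edge or a probe occluder (the probe may overlap the fish -- labels
    remain valid, emulating tail-touch frames where the filament occludes the
    body).
    """

    frame_size: tuple[int, int] = (256, 256)
    background_level: tuple[float, float] = (0.70, 0.95)
    fish_level: tuple[float, float] = (0.10, 0.40)
    body_length_frac: tuple[float, float] = (0.25, 0.45)  # of min frame side
    curvature: tuple[float, float] = (-200.0, 200.0)
    illumination_gradient: tuple[float, float] = (0.0, 0.15)
    noise_sd: tuple[float, float] = (0.0, 0.03)
    blur_sigma: tuple[float, float] = (0.4, 1.5)
    well_prob: float = 0.5
    probe_prob: float = 0.25


@dataclass
class TrajectoryScript:
    """Scripted ground-truth behavior for a synthetic movie.

    bout_schedule
        List of (start s, duration s, peak speed mm/s) swim bouts; the speed
        profile of each bout is a raised-cosine bump peaking at its midpoint.
        Bouts must not overlap.
    bend_schedule
        List of (peak time s, peak angle degrees) body bends; each is a
        raised-cosine bump of the rostral-caudal angle with total width
        ``bend_width_s``.  Bends must not overlap.
    """

    framerate: float = 100.0
    duration: float = 2.0
    bout_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    bend_schedule: list[tuple[float, float]] = field(default_factory=list)
    mm_per_px: float = 0.1
    bend_width_s: float = 0.08
    heading: float = 0.0

    def __post_init__(self) -> None:
        if self.framerate <= 0:
            raise ValueError("framerate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for start, dur, peak in self.bout_schedule:
            if not (0 <= start and start + dur <= self.duration):
                raise ValueError(f"bout ({start}, {dur}, {peak}) outside [0, {self.duration}]")
            if dur <= 0 or peak <= 0:
                raise ValueError("bout duration and peak speed must be > 0")
        spans = sorted((s, s + d) for s, d, _ in self.bout_schedule)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("bouts must not overlap")
        half = self.bend_width_s / 2
        for t, _angle in self.bend_schedule:
            if not (0 <= t <= self.duration):
                raise ValueError(f"bend at {t} s outside [0, {self.duration}]")
        bend_times = sorted(t for t, _ in self.bend_schedule)
        for a, b in zip(bend_times, bend_times[1:]):
            if b - a < 2 * half:
                raise ValueError("bends must not overlap")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.framerate))


def keypoint_arc_fractions(n_keypoints: int) -> np.ndarray:
    """Arc-length fractions of the K labeled keypoints, rostral to caudal.

    K >= 2 keypoints are evenly spaced at i/(K-1); a single keypoint sits near
    the head end (between the two eyes).
    """
    if not 1 <= n_keypoints <= 10:
        raise ValueError("n_keypoints must be in [1, 10]")
    if n_keypoints == 1:
        return np.array([SINGLE_KEYPOINT_FRACTION])
    return np.arange(n_keypoints) / (n_keypoints - 1)


def midline_points(pose: PoseParams, fractions: np.ndarray) -> np.ndarray:
    """(x, y) points at the given arc-length fractions of the body midline.

    The midline is a constant-curvature arc of length ``body_length`` whose
    tangent turns ``arc_curvature`` degrees in total, centered (in the mean
    sense) on ``pose.centroid`` and oriented so that the mid-arc tangent
    equals ``heading``.
    """
    fractions = np.asarray(fractions, dtype=float)
    length = pose.body_length
    theta0 = np.radians(pose.heading) - np.radians(pose.arc_curvature) / 2
    kappa = np.radians(pose.arc_curvature) / length  # turning per arc length

    def arc(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if abs(kappa) < 1e-12:
            x = s * np.cos(theta0)
            y = s * np.sin(theta0)
        else:
            theta = theta0 + kappa * s
            x = (np.sin(theta) - np.sin(theta0)) / kappa
            y = (-np.cos(theta) + np.cos(theta0)) / kappa
        return np.stack([x, y], axis=-1)

    # Center: the centroid is the mean of the midline, computed densely.
    dense = arc(np.linspace(0.0, length, 257))
    offset = np.asarray(pose.centroid, dtype=float) - dense.mean(axis=0)
    return arc(fractions * length) + offset


def _soft_disks(shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Coverage mask in [0, 1]: union of circles with ~1 px soft edges."""
    h, w = shape
    mask = np.zeros((h, w), dtype=float)
    for (cx, cy), r in zip(centers, radii):
        pad = r + 1.5
        x0, x1 = max(int(np.floor(cx - pad)), 0), min(int(np.ceil(cx + pad)) + 1, w)
        y0, y1 = max(int(np.floor(cy - pad)), 0), min(int(np.ceil(cy + pad)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy = np.arange(y0, y1, dtype=float)[:, None]
        xx = np.arange(x0, x1, dtype=float)[None, :]
        dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        local = np.clip(r + 0.5 - dist, 0.0, 1.0)
        np.maximum(mask[y0:y1, x0:x1], local, out=mask[y0:y1, x0:x1])
    return mask


def _render_background(scene: SceneSpec) -> np.ndarray:
    h, w = scene.frame_size
    img = np.full((h, w), scene.background_level, dtype=float)
    if scene.illumination_gradient:
        yy = np.linspace(0.0, 1.0, h)[:, None]
        xx = np.linspace(0.0, 1.0, w)[None, :]
        img += scene.illumination_gradient * ((xx + yy) / 2 - 0.5)
    if scene.well_edge is not None:
        (cx, cy), radius, darkness = scene.well_edge
        yy = np.arange(h, dtype=float)[:, None]
        xx = np.arange(w, dtype=float)[None, :]
        dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ring = np.clip(1.5 - np.abs(dist - radius), 0.0, 1.0)
        img = img * (1.0 - darkness * ring)
    if scene.probe is not None:
        (px, py), angle, half_width = scene.probe
        # A long capsule from the frame border ending at (px, py).
        direction = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle))])
        tip = np.array([px, py], dtype=float)
        length = float(np.hypot(h, w))  # long enough to exit the frame
        n_samples = max(int(length), 2)
        ts = np.linspace(0.0, length, n_samples)
        centers = tip - direction * ts[:, None]
        radii = np.full(n_samples, half_width)
        mask = _soft_disks((h, w), centers, radii)
        probe_level = scene.fish_level * 0.6
        img = img * (1.0 - mask) + probe_level * mask
    return img


def render_frame(
    pose: PoseParams, scene: SceneSpec, rng_seed: int = 0, n_keypoints: int = 7
) -> LabeledFrame:
    """Render one fish into one scene; deterministic for fixed inputs.

    Returns the grayscale image in [0, 1] and ``n_keypoints`` keypoints evenly
    spaced by arc length along the rendered midline, rostral to caudal.
    Raises :class:`PoseOutsideFrameError` when the body (including its width)
    does not fit inside the frame.
    """
    return _render_labeled(pose, scene, rng_seed, n_keypoints=n_keypoints)


def _render_labeled(
    pose: PoseParams,
    scene: SceneSpec,
    rng_seed: int,
    n_keypoints: int,
) -> LabeledFrame:
    h, w = scene.frame_size
    length = pose.body_length
    n_samples = max(int(np.ceil(length * 2)), 8)
    s_fracs = np.linspace(0.0, 1.0, n_samples)
    centers = midline_points(pose, s_fracs)
    profile_x = np.linspace(0.0, 1.0, len(pose.body_width_profile))
    radii = np.interp(s_fracs, profile_x, pose.body_width_profile) * length

    margin = radii.max() + 0.5
    if (
        centers[:, 0].min() - margin < 0
        or centers[:, 1].min() - margin < 0
        or centers[:, 0].max() + margin > w - 1
        or centers[:, 1].max() + margin > h - 1
    ):
        raise PoseOutsideFrameError(
            f"pose at centroid {pose.centroid} (length {length:.1f} px) "
            f"does not fit inside a {w}x{h} frame"
        )

    img = _render_background(scene)
    mask = _soft_disks((h, w), centers, radii)
    img = img * (1.0 - mask) + scene.fish_level * mask
    if scene.blur_sigma > 0:
        img = gaussian_filter(img, scene.blur_sigma, mode="nearest")
    if scene.noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rng_seed)))
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    kp_coords = midline_points(pose, keypoint_arc_fractions(n_keypoints))
    return LabeledFrame(image=img, keypoints=Keypoints(kp_coords), pose=pose, scene=scene)


def _sample_pose_and_scene(
    ranges: SceneRanges, rng: np.random.Generator
) -> tuple[PoseParams, SceneSpec]:
    h, w = ranges.frame_size
    side = min(h, w)
    length = rng.uniform(*ranges.body_length_frac) * side
    curvature = rng.uniform(*ranges.curvature)
    heading = rng.uniform(0.0, 360.0)
    # Keep the whole body inside the frame: the midline stays within
    # body_length / 2 of the centroid, plus the maximum half-width.
    margin = length / 2 + DEFAULT_WIDTH_PROFILE[0] * length + 2.0
    cx = rng.uniform(margin, w - 1 - margin)
    cy = rng.uniform(margin, h - 1 - margin)
    pose = PoseParams(
        centroid=(cx, cy),
        heading=heading,
        arc_curvature=curvature,
        body_length=length,
    )
    well = None
    if rng.uniform() < ranges.well_prob:
        radius = rng.uniform(0.42, 0.49) * side
        well = ((w / 2, h / 2), radius, rng.uniform(0.3, 0.8))
    probe = None
    if rng.uniform() < ranges.probe_prob:
        # Aim the probe at a point near the fish so occlusions actually occur.
        target = (
            cx + rng.normal(0.0, length / 2),
            cy + rng.normal(0.0, length / 2),
        )
        probe = (target, rng.uniform(0.0, 360.0), rng.uniform(1.5, 4.0))
    scene = SceneSpec(
        frame_size=ranges.frame_size,
        background_level=rng.uniform(*ranges.background_level),
        fish_level=rng.uniform(*ranges.fish_level),
        well_edge=well,
        probe=probe,
        illumination_gradient=rng.uniform(*ranges.illumination_gradient),
        noise_sd=rng.uniform(*ranges.noise_sd),
        blur_sigma=rng.uniform(*ranges.blur_sigma),
    )
    return pose, scene


def generate_dataset(
    n_frames: int,
    n_keypoints: int = 7,
    scene_ranges: SceneRanges | None = None,
    seed: int = 0,
) -> PoseDataset:
    """Generate a randomized labeled dataset of ``n_frames`` frames.

    Poses and scenes are drawn uniformly from ``scene_ranges`` (defaults
    emulate diverse recording conditions: varying lighting, contrast, focus,
    well edges, and occasional probe occluders).  Fully reproducible: frame i
    uses the root seed with spawn key (i,).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 1 <= n_keypoints <= 10:
        raise ValueError("n_keypoints must be in [1, 10]")
    ranges = scene_ranges or SceneRanges()
    frames = []
    for i in range(n_frames):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,))))
        pose, scene = _sample_pose_and_scene(ranges, rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(_render_labeled(pose, scene, noise_seed, n_keypoints))
    return PoseDataset(
        frames=frames, n_keypoints=n_keypoints, frame_size=ranges.frame_size, seed=seed
    )


def _script_speed_profile(script: TrajectoryScript, times: np.ndarray) -> np.ndarray:
    """Continuous scripted speed (mm/s) at the given times."""
    v = np.zeros_like(times)
    for start, dur, peak in script.bout_schedule:
        in_bout = (times >= start) & (times < start + dur)
        phase = (times[in_bout] - start) / dur
        v[in_bout] = np.maximum(v[in_bout], peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase)))
    return v


def _script_angle_profile(script: TrajectoryScript, times: np.ndarray) -> np.ndarray:
    """Scripted rostral-caudal angle (degrees) at the given times."""
    a = np.zeros_like(times)
    half = script.bend_width_s / 2
    for peak_time, peak_angle in script.bend_schedule:
        in_bend = np.abs(times - peak_time) < half
        phase = (times[in_bend] - peak_time) / half  # in (-1, 1)
        a[in_bend] = peak_angle * 0.5 * (1.0 + np.cos(np.pi * phase))
    return a


def generate_trajectory_movie(
    script: TrajectoryScript,
    scene: SceneSpec,
    seed: int = 0,
    n_keypoints: int = 7,
    body_length: float | None = None,
    start: tuple[float, float] | None = None,
    render: bool = True,
) -> tuple[np.ndarray | None, TrajectorySeries]:
    """Render a scripted movie and its exact ground-truth trajectory.

    The fish translates along ``script.heading`` with the scripted speed
    profile (trapezoid-integrated per frame) and bends per the scripted
    rostral-caudal angle bumps.  The scripted path drives the *reference*
    (most rostral) keypoint -- bends swing the rest of the body around it --
    so the speed measured at that keypoint reproduces the scripted profile
    exactly even while the body bends.  The returned ground truth carries the
    exact per-frame keypoints implied by the script; ``frames`` is a
    (T, H, W) array, or None with ``render=False`` (useful for network-free
    kinematics validation).

    A bout that would carry the fish off the frame raises a ValueError naming
    the offending bout.
    """
    h, w = scene.frame_size
    side = min(h, w)
    length = body_length if body_length is not None else 0.3 * side
    n = script.n_frames
    dt = 1.0 / script.framerate
    times = np.arange(n) * dt

    v = _script_speed_profile(script, times)  # mm/s at frame times
    # Per-frame displacement via the trapezoid rule, in px.
    step_mm = (v[:-1] + v[1:]) / 2 * dt
    step_px = np.concatenate([[0.0], step_mm / script.mm_per_px])
    path = np.cumsum(step_px)
    direction = np.array([np.cos(np.radians(script.heading)), np.sin(np.radians(script.heading))])

    margin = length + DEFAULT_WIDTH_PROFILE[0] * length + 2.0
    if start is None:
        start_pt = np.array([margin + 1.0, h / 2], dtype=float)
    else:
        start_pt = np.asarray(start, dtype=float)
    anchors = start_pt[None, :] + path[:, None] * direction[None, :]

    out_x = (anchors[:, 0] < margin) | (anchors[:, 0] > w - 1 - margin)
    out_y = (anchors[:, 1] < margin) | (anchors[:, 1] > h - 1 - margin)
    bad = np.flatnonzero(out_x | out_y)
    if bad.size:
        t_bad = times[bad[0]]
        for idx, (s, d, p) in enumerate(script.bout_schedule):
            if s <= t_bad <= s + d + dt:
                raise ValueError(
                    f"bout {idx} (start {s} s, duration {d} s, peak {p} mm/s) "
                    f"moves the fish off the frame at t={t_bad:.3f} s"
                )
        raise ValueError(f"trajectory leaves the frame at t={t_bad:.3f} s")

    chord_factor = (n_keypoints - 2) / (n_keypoints - 1) if n_keypoints >= 3 else 1.0
    angles = _script_angle_profile(script, times)

    frames = np.empty((n, h, w), dtype=float) if render else None
    keypoints = np.empty((n, n_keypoints, 2), dtype=float)
    fracs = keypoint_arc_fractions(n_keypoints)
    for t in range(n):
        # The scripted angle is the chord-sum (rostral-caudal) angle; the
        # underlying arc turns by the factor (K-1)/(K-2) more.  The pose is
        # anchored so its most rostral keypoint follows the scripted path.
        probe_pose = PoseParams(
            centroid=(0.0, 0.0),
            heading=script.heading,
            arc_curvature=float(angles[t]) / chord_factor,
            body_length=length,
        )
        anchor_offset = midline_points(probe_pose, fracs[:1])[0]
        centroid = anchors[t] - anchor_offset
        pose = replace(probe_pose, centroid=(float(centroid[0]), float(centroid[1])))
        keypoints[t] = midline_points(pose, fracs)
        if render:
            noise_seed = int(
                np.random.Generator(
                    np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(t,)))
                ).integers(0, 2**31 - 1)
            )
            frames[t] = _render_labeled(pose, scene, noise_seed, n_keypoints).image
    truth = TrajectorySeries(
        keypoints=keypoints,
        framerate=script.framerate,
        mm_per_px=script.mm_per_px,
    )
    return frames, truth
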