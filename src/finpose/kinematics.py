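"""Kinematic analysis of tracked larval-zebrafish trajectories.

Turns per-frame keypoint coordinates into the standard behavioral readouts:
instantaneous speed, the signed rostral-caudal body-bend angle, high-amplitude
body bends, swim bouts, and summaries of responses to touch or light/dark
stimuli.

Units and conventions
---------------------
Coordinates are 0-based pixel centers, x rightward, y downward.  Angles are in
degrees; the rostral-caudal angle is the summed signed turning angle along the
head-to-tail midline chords, positive for counterclockwise turning in image
coordinates.  Speeds are in mm/s via the recording's ``mm_per_px`` calibration
(which must be supplied -- there is no hidden default) and framerate
(typically 1000 Hz for touch-evoked escape responses, 100 Hz for multiwell
visuomotor recordings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySeries",
    "KinematicConfig",
    "BendEvent",
    "Bout",
    "compute_speed",
    "smooth_series",
    "rostral_caudal_angle",
    "detect_bends",
    "detect_bouts",
    "stimulus_summary",
    "response_summary",
    "trajectory_table",
    "events_table",
]


@dataclass
class TrajectorySeries:
    """Per-frame keypoints for one animal with time base and calibration.

    keypoints
        Array of shape (T, K, 2) in pixels (plate or frame coordinates).
    framerate
        Frames per second of the recording.
    mm_per_px
        Spatial calibration; must be positive and explicitly supplied.
    stimulus_marks
        Optional mapping of label -> time in seconds (e.g. ``{"light_on":
        30.0, "dark_on": 90.0}``) delimiting recording periods.
    confidence
        Optional (T, K) decoded peak values.
    """

    keypoints: np.ndarray
    framerate: float
    mm_per_px: float
    stimulus_marks: dict[str, float] = field(default_factory=dict)
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 3 or self.keypoints.shape[2] != 2:
            raise ValueError("keypoints must have shape (T, K, 2)")
        if self.framerate <= 0:
            raise ValueError("framerate must be > 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0 (supply the calibration explicitly)")

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.framerate


@dataclass
class KinematicConfig:
    """Thresholds and windows of the kinematic readouts.

    bend_threshold
        Absolute peak rostral-caudal angle (degrees) at or above which a body
        bend counts as high-amplitude.  Default 110.
    bout_threshold
        Speed (mm/s) a fish must exceed to be in a swim bout.  Default 2.
    stim_window
        Length (s) of the post-stimulus window for maximum-speed summaries.
        Default 5.
    smooth_window
        Mean-filter window (s) for presentation speed traces.  Default 1.
    reference_keypoint
        Index of the keypoint used for position/speed (0 = most rostral).
    """

    bend_threshold: float = 110.0
    bout_threshold: float = 2.0
    stim_window: float = 5.0
    smooth_window: float = 1.0
    reference_keypoint: int = 0

    def __post_init__(self) -> None:
        for name in ("bend_threshold", "bout_threshold", "stim_window", "smooth_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class BendEvent:
    """One body-bend half-beat: the signed peak of a same-sign angle run."""

    peak_time: float
    peak_angle: float
    is_high_amplitude: bool


@dataclass
class Bout:
    """One swim bout: a maximal run of frames with speed above threshold."""

    start_time: float
    end_time: float
    duration: float
    peak_speed: float


def compute_speed(traj: TrajectorySeries, cfg: KinematicConfig | None = None) -> np.ndarray:
    """Instantaneous speed (mm/s) of the reference keypoint; first frame 0."""
    cfg = cfg or KinematicConfig()
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    pos = traj.keypoints[:, cfg.reference_keypoint, :]
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speed = np.concatenate([[0.0], step * traj.mm_per_px * traj.framerate])
    return speed


def smooth_series(x: np.ndarray, window_s: float, framerate: float) -> np.ndarray:
    """Centered moving mean with the window shrinking at the edges.

    The window spans ``half = round(window_s * framerate / 2)`` frames on each
    side (2*half + 1 frames in the interior), the discrete analogue of a
    sliding window of ``window_s`` seconds.
    """
    x = np.asarray(x, dtype=float)
    if window_s * framerate < 1:
        raise ValueError("window must span at least one frame")
    half = int(round(window_s * framerate / 2))
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def rostral_caudal_angle(kp: np.ndarray) -> float:
    """Signed body-bend angle (degrees) of one pose, head to tail.

    Sums the signed turning angle between consecutive midline chord vectors;
    a straight body gives 0, counterclockwise bending (image coordinates) is
    positive, and a mirror-image pose negates the angle.  Requires K >= 3
    ordered rostral-to-caudal keypoints with no coincident neighbors.
    """
    kp = np.asarray(kp, dtype=float)
    if kp.ndim != 2 or kp.shape[1] != 2 or kp.shape[0] < 3:
        raise ValueError("need at least 3 ordered (x, y) keypoints")
    seg = np.diff(kp, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths == 0):
        raise ValueError("coincident consecutive keypoints")
    a, b = seg[:-1], seg[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.sum(a * b, axis=1)
    return float(np.degrees(np.arctan2(cross, dot)).sum())


def angle_series(traj: TrajectorySeries) -> np.ndarray:
    """Rostral-caudal angle (degrees) for every frame of a trajectory."""
    return np.array([rostral_caudal_angle(traj.keypoints[t]) for t in range(traj.n_frames)])


def detect_bends(
    angles: np.ndarray,
    framerate: float,
    cfg: KinematicConfig | None = None,
) -> list[BendEvent]:
    """Detect body-bend peaks as extrema of same-sign runs of the angle series.

    The series is split into maximal runs of constant nonzero sign (zeros
    separate runs); each run contributes one event at its maximum |angle|
    (earliest frame on ties).  Events with ``|peak| >= bend_threshold`` are
    flagged high-amplitude.
    """
    cfg = cfg or KinematicConfig()
    angles = np.asarray(angles, dtype=float)
    events: list[BendEvent] = []
    sign = np.sign(angles)
    t = 0
    n = angles.size
    while t < n:
        if sign[t] == 0:
            t += 1
            continue
        start = t
        while t < n and sign[t] == sign[start]:
            t += 1
        run = np.abs(angles[start:t])
        peak_idx = start + int(np.argmax(run))  # argmax: earliest on ties
        peak = float(angles[peak_idx])
        events.append(
            BendEvent(
                peak_time=peak_idx / framerate,
                peak_angle=peak,
                is_high_amplitude=abs(peak) >= cfg.bend_threshold,
            )
        )
    return events


def bend_summary(events: list[BendEvent], angles: np.ndarray, framerate: float) -> dict:
    """First-bend and maximum-angle summaries of a response.

    Reports the signed peak angle and timing of the first bend, the maximum
    |angle| across the whole series and its time (earliest frame on ties), and
    the count of high-amplitude bends.
    """
    angles = np.asarray(angles, dtype=float)
    out: dict[str, float | int | None] = {
        "first_bend_angle": None,
        "first_bend_time": None,
        "max_angle": None,
        "max_angle_time": None,
        "n_high_amplitude": int(sum(e.is_high_amplitude for e in events)),
        "any_high_amplitude": any(e.is_high_amplitude for e in events),
    }
    if events:
        out["first_bend_angle"] = events[0].peak_angle
        out["first_bend_time"] = events[0].peak_time
    if angles.size:
        i = int(np.argmax(np.abs(angles)))
        out["max_angle"] = float(np.abs(angles[i]))
        out["max_angle_time"] = i / framerate
    return out


def detect_bouts(
    speed: np.ndarray,
    framerate: float,
    cfg: KinematicConfig | None = None,
) -> list[Bout]:
    """Segment swim bouts: maximal runs of frames with speed > threshold.

    A bout begins when speed exceeds the threshold (strict >) and ends when it
    drops below again; a run still open at the end of the series closes at the
    last frame.  Duration is the run length over the framerate; single-frame
    bouts are allowed.
    """
    cfg = cfg or KinematicConfig()
    speed = np.asarray(speed, dtype=float)
    above = speed > cfg.bout_threshold
    bouts: list[Bout] = []
    t = 0
    n = speed.size
    while t < n:
        if not above[t]:
            t += 1
            continue
        start = t
        while t < n and above[t]:
            t += 1
        bouts.append(
            Bout(
                start_time=start / framerate,
                end_time=(t - 1) / framerate,
                duration=(t - start) / framerate,
                peak_speed=float(np.max(speed[start:t])),
            )
        )
    return bouts


def stimulus_summary(
    traj: TrajectorySeries,
    mark: float,
    cfg: KinematicConfig | None = None,
) -> dict:
    """Post-stimulus summary over ``[mark, mark + stim_window)``.

    Returns the maximum raw (unsmoothed) speed in the window, the bout count,
    and the mean bout duration and mean bout peak speed within the window
    (NaN when the window holds no bouts).  A window extending beyond the
    recording is truncated with a warning.
    """
    cfg = cfg or KinematicConfig()
    times = traj.times
    if not (times[0] <= mark <= times[-1]):
        raise ValueError(f"stimulus mark {mark} s outside recording [0, {times[-1]:.3f}] s")
    speed = compute_speed(traj, cfg)
    end = mark + cfg.stim_window
    if end > times[-1] + 1.0 / traj.framerate:
        warnings.warn(
            f"stimulus window [{mark}, {end}) s exceeds the recording; truncating",
            stacklevel=2,
        )
    in_window = (times >= mark) & (times < end)
    window_speed = speed[in_window]
    offset_frames = int(np.searchsorted(times, mark))
    bouts = detect_bouts(window_speed, traj.framerate, cfg)
    bouts = [
        Bout(
            start_time=b.start_time + offset_frames / traj.framerate,
            end_time=b.end_time + offset_frames / traj.framerate,
            duration=b.duration,
            peak_speed=b.peak_speed,
        )
        for b in bouts
    ]
    return {
        "max_speed": float(np.max(window_speed)) if window_speed.size else float("nan"),
        "bout_count": len(bouts),
        "mean_bout_duration": float(np.mean([b.duration for b in bouts])) if bouts else float("nan"),
        "mean_bout_peak_speed": float(np.mean([b.peak_speed for b in bouts])) if bouts else float("nan"),
        "bouts": bouts,
    }


def period_summaries(traj: TrajectorySeries, cfg: KinematicConfig | None = None) -> pd.DataFrame:
    """Per-period bout statistics, with periods delimited by stimulus marks.

    Periods run from each mark (and from time 0) to the next mark (or the end
    of the recording); rows report bout count, mean duration, and mean peak
    speed per period.
    """
    cfg = cfg or KinematicConfig()
    speed = compute_speed(traj, cfg)
    times = traj.times
    marks = sorted(traj.stimulus_marks.items(), key=lambda kv: kv[1])
    edges = [("start", 0.0)] + [(k, v) for k, v in marks if v > 0.0]
    rows = []
    for i, (label, t0) in enumerate(edges):
        t1 = edges[i + 1][1] if i + 1 < len(edges) else times[-1] + 1.0 / traj.framerate
        sel = (times >= t0) & (times < t1)
        bouts = detect_bouts(speed[sel], traj.framerate, cfg)
        rows.append(
            {
                "period": label,
                "start_s": t0,
                "end_s": t1,
                "bout_count": len(bouts),
                "mean_bout_duration": float(np.mean([b.duration for b in bouts])) if bouts else float("nan"),
                "mean_bout_peak_speed": float(np.mean([b.peak_speed for b in bouts])) if bouts else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def response_summary(traj: TrajectorySeries, cfg: KinematicConfig | None = None) -> dict:
    """Whole-response summary for a trimmed single-response recording.

    Duration is the frame count over the framerate; distance is the path
    length of the reference keypoint in mm; ``progress`` maps each frame to
    t/duration in [0, 1]; bend summaries require K >= 3 keypoints.
    """
    cfg = cfg or KinematicConfig()
    n = traj.n_frames
    duration = n / traj.framerate
    pos = traj.keypoints[:, cfg.reference_keypoint, :]
    distance = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum() * traj.mm_per_px)
    progress = np.arange(1, n + 1) / n
    out = {"duration": duration, "distance": distance, "progress": progress}
    if traj.n_keypoints >= 3:
        angles = angle_series(traj)
        events = detect_bends(angles, traj.framerate, cfg)
        out["angles"] = angles
        out["bends"] = events
        out.update(bend_summary(events, angles, traj.framerate))
    return out


def trajectory_table(traj: TrajectorySeries, cfg: KinematicConfig | None = None) -> pd.DataFrame:
    """Tidy per-frame table: coordinates, speed, and angles.

    Columns: frame, time_s, x_i/y_i per keypoint, speed_mm_s, and (for K >= 3)
    rostral_caudal_angle_deg plus each chord's absolute orientation
    (segment_angle_i_deg), for downstream statistics tools.
    """
    cfg = cfg or KinematicConfig()
    n, k = traj.n_frames, traj.n_keypoints
    data: dict[str, np.ndarray] = {
        "frame": np.arange(n),
        "time_s": traj.times,
    }
    for i in range(k):
        data[f"x_{i}"] = traj.keypoints[:, i, 0]
        data[f"y_{i}"] = traj.keypoints[:, i, 1]
    data["speed_mm_s"] = compute_speed(traj, cfg)
    if k >= 3:
        data["rostral_caudal_angle_deg"] = angle_series(traj)
    if k >= 2:
        seg = np.diff(traj.keypoints, axis=1)  # (T, K-1, 2)
        orient = np.degrees(np.arctan2(seg[:, :, 1], seg[:, :, 0]))
        for i in range(k - 1):
            data[f"segment_angle_{i}_deg"] = orient[:, i]
    return pd.DataFrame(data)


def events_table(traj: TrajectorySeries, cfg: KinematicConfig | None = None) -> pd.DataFrame:
    """Tidy event table of swim bouts and body bends for one animal."""
    cfg = cfg or KinematicConfig()
    speed = compute_speed(traj, cfg)
    rows = []
    for b in detect_bouts(speed, traj.framerate, cfg):
        rows.append(
            {
                "event": "bout",
                "start_s": b.start_time,
                "end_s": b.end_time,
                "duration_s": b.duration,
                "peak": b.peak_speed,
                "high_amplitude": pd.NA,
            }
        )
    if traj.n_keypoints >= 3:
        for e in detect_bends(angle_series(traj), traj.framerate, cfg):
            rows.append(
                {
                    "event": "bend",
                    "start_s": e.peak_time,
                    "end_s": e.peak_time,
                    "duration_s": 0.0,
                    "peak": e.peak_angle,
                    "high_amplitude": e.is_high_amplitude,
                }
            )
    return pd.DataFrame(
        rows, columns=["event", "start_s", "end_s", "duration_s", "peak", "high_amplitude"]
    )
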