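"""Reading and writing recordings, labeled datasets, and manifests.

The canonical, dependency-light movie format is a directory of
lexicographically ordered PNG or TIFF frames; common video files are read
through imageio's optional plugins when available.  Images load as
single-channel float grids in [0, 1] (16-bit PNGs scale by 65535, 8-bit by
255; RGB inputs collapse to the channel average with a warning).

A labeled dataset is a directory::

    frames/000000.png ...   16-bit grayscale PNG
    labels.csv              frame, keypoint_index, x, y  (0-based pixel centers)
    manifest.yaml           frame size, K, seed, generator version

Scripted movies are the same layout with ``truth.csv`` holding the per-frame
ground-truth keypoints.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .codec import Keypoints
from .synthetic import LabeledFrame, PoseDataset

__all__ = [
    "load_image",
    "load_frames",
    "save_image",
    "save_dataset",
    "load_dataset",
    "save_movie",
    "load_movie",
]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def load_image(path) -> np.ndarray:
    """One image as a single-channel float grid in [0, 1]."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL mode I;16 loads as I (int32)
        out = arr.astype(float) / 65535.0
    else:
        out = np.clip(arr.astype(float), 0.0, 1.0)
    if out.ndim == 3:
        warnings.warn(f"{path.name}: RGB input converted by channel average", stacklevel=2)
        out = out.mean(axis=2)
    return out


def load_frames(path, framerate: float | None = None) -> np.ndarray:
    """A movie as a (T, H, W) float array in [0, 1].

    ``path`` is a directory of PNG/TIFF frames (ordered lexicographically) or
    a video file (delegated to imageio, if its plugins can read it).  All
    frames must share one size; offenders are listed in the error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = []
        bad = []
        first_shape = None
        for f in files:
            try:
                img = load_image(f)
            except Exception as exc:  # noqa: BLE001 - report offenders together
                bad.append(f"{f.name}: {exc}")
                continue
            if first_shape is None:
                first_shape = img.shape
            elif img.shape != first_shape:
                bad.append(f"{f.name}: size {img.shape} != {first_shape}")
                continue
            frames.append(img)
        if bad:
            raise ValueError("unreadable or mixed-size frames:\n  " + "\n  ".join(bad))
        return np.stack(frames)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 4:  # (T, H, W, C)
        warnings.warn(f"{path.name}: color video converted by channel average", stacklevel=2)
        arr = arr.mean(axis=3)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    data = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(data, mode="I;16").save(path)


def _labels_frame(coords_per_frame: list[np.ndarray]) -> pd.DataFrame:
    rows = []
    for t, coords in enumerate(coords_per_frame):
        for k, (x, y) in enumerate(coords):
            rows.append({"frame": t, "keypoint_index": k, "x": x, "y": y})
    return pd.DataFrame(rows)


def save_dataset(ds: PoseDataset, outdir) -> Path:
    """Write a labeled dataset as frames/ + labels.csv + manifest.yaml."""
    outdir = Path(outdir)
    frame_dir = outdir / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(ds.frames):
        save_image(frame.image, frame_dir / f"{i:06d}.png")
    _labels_frame([f.keypoints.coords for f in ds.frames]).to_csv(
        outdir / "labels.csv", index=False
    )
    h, w = ds.frame_size
    manifest = {
        "format_version": 1,
        "generator": f"finpose {__version__}",
        "frame_height": int(h),
        "frame_width": int(w),
        "n_frames": len(ds),
        "n_keypoints": int(ds.n_keypoints),
        "seed": ds.seed,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def load_dataset(path) -> PoseDataset:
    """Load a labeled dataset written by :func:`save_dataset`."""
    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    labels = pd.read_csv(path / "labels.csv")
    images = load_frames(path / "frames")
    k = int(manifest["n_keypoints"])
    frames = []
    for t in range(images.shape[0]):
        sub = labels[labels["frame"] == t].sort_values("keypoint_index")
        if len(sub) != k:
            raise ValueError(f"frame {t}: expected {k} labels, found {len(sub)}")
        frames.append(
            LabeledFrame(image=images[t], keypoints=Keypoints(sub[["x", "y"]].to_numpy()))
        )
    return PoseDataset(
        frames=frames,
        n_keypoints=k,
        frame_size=(int(manifest["frame_height"]), int(manifest["frame_width"])),
        seed=manifest.get("seed"),
    )


def save_movie(frames: np.ndarray, truth, outdir, framerate: float, mm_per_px: float) -> Path:
    """Write a scripted movie: frames/ + truth.csv + manifest.yaml."""
    outdir = Path(outdir)
    frame_dir = outdir / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    for i in range(frames.shape[0]):
        save_image(frames[i], frame_dir / f"{i:06d}.png")
    _labels_frame(list(truth.keypoints)).to_csv(outdir / "truth.csv", index=False)
    manifest = {
        "format_version": 1,
        "generator": f"finpose {__version__}",
        "frame_height": int(frames.shape[1]),
        "frame_width": int(frames.shape[2]),
        "n_frames": int(frames.shape[0]),
        "n_keypoints": int(truth.keypoints.shape[1]),
        "framerate": float(framerate),
        "mm_per_px": float(mm_per_px),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def load_movie(path):
    """Load a scripted movie directory; returns (frames, TrajectorySeries)."""
    from .kinematics import TrajectorySeries

    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    frames = load_frames(path / "frames")
    truth = pd.read_csv(path / "truth.csv")
    k = int(manifest["n_keypoints"])
    t_max = int(truth["frame"].max()) + 1
    kp = np.zeros((t_max, k, 2))
    for _, row in truth.iterrows():
        kp[int(row["frame"]), int(row["keypoint_index"])] = (row["x"], row["y"])
    series = TrajectorySeries(
        keypoints=kp,
        framerate=float(manifest["framerate"]),
        mm_per_px=float(manifest["mm_per_px"]),
    )
    return frames, series
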