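"""Applying a trained network to new recordings.

Each ROI is letterboxed (aspect-preserving resize plus background-median
padding) to the network's input size, pushed through a forward pass in
evaluation mode, decoded to subpixel keypoints, and mapped back through the
letterbox and the ROI offset to plate pixel coordinates.  The coordinate
chain is exactly invertible, so tracking error is model error only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as ndi_zoom

from .codec import HeatmapStack, decode_heatmaps
from .kinematics import TrajectorySeries
from .nn.model import Network
from .roi import Roi, RoiGrid, crop_roi

__all__ = ["Letterbox", "letterbox", "track_movie"]


@dataclass(frozen=True)
class Letterbox:
    """The resize-plus-pad placement of an ROI inside the network input."""

    scale: float
    pad_x: float
    pad_y: float

    def to_network(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords * self.scale + np.array([self.pad_x, self.pad_y])

    def to_roi(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (coords - np.array([self.pad_x, self.pad_y])) / self.scale


def letterbox(img: np.ndarray, size: tuple[int, int]) -> tuple[np.ndarray, Letterbox]:
    """Aspect-preserving resize of ``img`` into ``size`` (H, W), median-padded.

    Coordinates map as ``x_net = x_roi * scale + pad_x`` (pixel centers).
    """
    h, w = img.shape
    out_h, out_w = size
    scale = min(out_h / h, out_w / w)
    new_h, new_w = int(round(h * scale)), int(round(w * scale))
    if (new_h, new_w) != (h, w):
        resized = ndi_zoom(img, (new_h / h, new_w / w), order=1, grid_mode=True, mode="nearest")
    else:
        resized = img
    canvas = np.full((out_h, out_w), float(np.median(img)))
    off_y = (out_h - new_h) // 2
    off_x = (out_w - new_w) // 2
    canvas[off_y : off_y + new_h, off_x : off_x + new_w] = resized
    # Pixel-center mapping: x_net = (x_roi + 0.5) * s - 0.5 + off_x
    eff_scale = new_w / w  # == new_h / h up to rounding; aspect preserved
    return canvas, Letterbox(scale=eff_scale, pad_x=off_x + (eff_scale - 1) / 2, pad_y=off_y + (eff_scale - 1) / 2)


def track_movie(
    frames: np.ndarray,
    net: Network,
    rois: RoiGrid | list[Roi],
    framerate: float,
    mm_per_px: float,
    stats=None,
    batch_size: int = 16,
    heatmaps_override=None,
) -> list[TrajectorySeries]:
    """Track one animal per ROI across a movie.

    ``stats`` (a :class:`finpose.augment.SplitStats`) standardizes inputs the
    same way the network saw them in training.  ``heatmaps_override`` is a
    plumbing hook for tests: a callable mapping the network-input image to a
    heatmap stack, bypassing the network.  Returns one
    :class:`TrajectorySeries` per ROI in plate pixel coordinates, with decoded
    confidences retained.
    """
    roi_list = list(rois.rois) if isinstance(rois, RoiGrid) else list(rois)
    cfg = net.cfg
    n_frames = frames.shape[0]
    out: list[TrajectorySeries] = []
    for roi in roi_list:
        coords = np.zeros((n_frames, cfg.O, 2))
        confs = np.zeros((n_frames, cfg.O))
        inputs = []
        boxes = []
        for t in range(n_frames):
            sub, _offset = crop_roi(frames[t], roi)
            canvas, box = letterbox(sub, (cfg.H, cfg.W))
            if stats is not None:
                canvas = (canvas - stats.mean) / stats.sd
            inputs.append(canvas)
            boxes.append(box)
        x = np.stack(inputs)[:, None].astype(np.float32)
        for start in range(0, n_frames, batch_size):
            chunk = x[start : start + batch_size]
            if heatmaps_override is not None:
                pred = np.stack([heatmaps_override(chunk[i, 0]) for i in range(chunk.shape[0])])
            else:
                pred = net.forward(chunk, training=False)
            for i in range(pred.shape[0]):
                t = start + i
                decoded = decode_heatmaps(HeatmapStack(pred[i]))
                roi_coords = boxes[t].to_roi(decoded.coords)
                coords[t] = roi_coords + np.array([roi.x0, roi.y0])
                confs[t] = decoded.confidence
        out.append(
            TrajectorySeries(
                keypoints=coords,
                framerate=framerate,
                mm_per_px=mm_per_px,
                confidence=confs,
            )
        )
    return out
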