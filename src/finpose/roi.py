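"""Multiwell region-of-interest grids.

Multiwell recordings (typically 24-well plates, 4 rows x 6 columns) are
analyzed one animal per ROI: a regular grid of equal-sized circular or square
regions inside an outer bounding rectangle.  Cropping returns the subimage
plus the offset that maps ROI-local keypoints back to plate coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Roi", "RoiGrid", "make_roi_grid", "crop_roi"]


@dataclass(frozen=True)
class Roi:
    """One region of interest: top-left corner and size, in plate pixels."""

    x0: int
    y0: int
    width: int
    height: int
    shape: str = "circle"

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + (self.width - 1) / 2, self.y0 + (self.height - 1) / 2)


@dataclass(frozen=True)
class RoiGrid:
    rows: int
    cols: int
    bounds: tuple[int, int, int, int]  # x0, y0, width, height
    roi_shape: str
    rois: tuple[Roi, ...]

    def __len__(self) -> int:
        return len(self.rois)


def make_roi_grid(
    rows: int,
    cols: int,
    bounds: tuple[int, int, int, int],
    shape: str = "circle",
) -> RoiGrid:
    """Regular grid of ``rows x cols`` equal, non-overlapping ROIs."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if shape not in ("circle", "square"):
        raise ValueError("shape must be 'circle' or 'square'")
    x0, y0, width, height = bounds
    roi_w = width // cols
    roi_h = height // rows
    if roi_w < 1 or roi_h < 1:
        raise ValueError("bounds too small for the requested grid")
    rois = []
    for r in range(rows):
        for c in range(cols):
            rois.append(Roi(x0 + c * roi_w, y0 + r * roi_h, roi_w, roi_h, shape))
    return RoiGrid(rows=rows, cols=cols, bounds=bounds, roi_shape=shape, rois=tuple(rois))


def crop_roi(frame: np.ndarray, roi: Roi) -> tuple[np.ndarray, tuple[int, int]]:
    """ROI subimage plus the (x, y) offset back to plate coordinates."""
    h, w = frame.shape
    if roi.x0 < 0 or roi.y0 < 0 or roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValueError(f"ROI {roi} outside the {w}x{h} frame")
    sub = frame[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return sub, (roi.x0, roi.y0)
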