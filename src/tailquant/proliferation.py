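"""Mitotic-figure counting from phospho-histone-H3 immunofluorescence.

Maximum-intensity projections are thresholded, connected components are
labelled (8-connectivity) and counted as mitotic figures when they are
strictly larger than 50 μm² and their centroid lies within 500 μm of the
caudal end of the larva.  Both cut-offs are parameters so the filter is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import CalibratedImage, Point2D, UnsupportedImageError

__all__ = ["SpotFilterParams", "SpotCountResult", "max_project", "detect_spots"]


@dataclass(frozen=True)
class SpotFilterParams:
    """Size and distance filters for mitotic-spot counting.

    ``min_area_um2`` is a strict lower bound ("greater than 50 μm²");
    ``max_dist_um`` is inclusive ("within 500 μm of the caudal end").
    ``threshold`` is ``"auto"`` (Otsu) or an absolute intensity; pixels
    strictly above it are foreground.
    """

    caudal_point: Point2D
    min_area_um2: float = 50.0
    max_dist_um: float = 500.0
    threshold: float | str = "auto"

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be non-negative")
        if self.max_dist_um <= 0:
            raise ValueError("max_dist_um must be positive")


@dataclass(frozen=True)
class SpotCountResult:
    """Filtered mitotic-figure count plus the per-spot audit table."""

    count: int
    spots: pd.DataFrame  # label, area_um2, centroid_x, centroid_y, distance_um, passed


_SPOT_COLUMNS = ["label", "area_um2", "centroid_x", "centroid_y", "distance_um", "passed"]


def max_project(stack: Sequence[CalibratedImage]) -> CalibratedImage:
    """Per-pixel maximum across z-slices of identical geometry."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    first = stack[0]
    for sl in stack[1:]:
        if sl.shape != first.shape or sl.pixels.ndim != first.pixels.ndim:
            raise ValueError("stack slices have mismatched dimensions")
        if sl.calibration != first.calibration:
            raise ValueError("stack slices have mismatched calibration")
    proj = np.maximum.reduce([sl.pixels for sl in stack])
    return CalibratedImage(proj, first.calibration)


def detect_spots(image: CalibratedImage, params: SpotFilterParams) -> SpotCountResult:
    """Count bright spots passing the area and caudal-distance filters.

    A blank image yields a count of 0 (no error).  Distances are from the
    spot centroid, the standard object location, to the caudal landmark.
    """
    if image.is_rgb:
        raise UnsupportedImageError("spot detection expects a single-channel image")
    h, w = image.shape
    cp = params.caudal_point
    if not (0 <= cp.x <= w and 0 <= cp.y <= h):
        raise ValueError("caudal point lies outside the image")
    img = image.pixels
    if params.threshold == "auto":
        if img.min() == img.max():
            return SpotCountResult(count=0, spots=pd.DataFrame(columns=_SPOT_COLUMNS))
        fg = img > threshold_otsu(img)
    else:
        fg = img > float(params.threshold)
    labels = label(fg, connectivity=2)
    px = image.calibration.pixel_size_um
    rows = []
    for region in regionprops(labels):
        area_um2 = region.area * image.calibration.area_factor
        cy, cx = region.centroid  # (row, col) means of pixel indices
        cx, cy = cx + 0.5, cy + 0.5  # pixel-centre convention
        dist_um = np.hypot(cx - cp.x, cy - cp.y) * px
        passed = area_um2 > params.min_area_um2 and dist_um <= params.max_dist_um
        rows.append(
            {
                "label": region.label,
                "area_um2": area_um2,
                "centroid_x": cx,
                "centroid_y": cy,
                "distance_um": dist_um,
                "passed": passed,
            }
        )
    spots = pd.DataFrame(rows, columns=_SPOT_COLUMNS)
    return SpotCountResult(count=int(spots["passed"].sum()) if len(spots) else 0, spots=spots)
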