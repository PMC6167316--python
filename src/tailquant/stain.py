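"""RGB-threshold quantification of chromogenic in situ staining area.

The oxidised-BCIP precipitate has a characteristic blue; an RGB threshold
sets an intensity window ``[min, max]`` (inclusive at both ends) on each
of the red, green and blue channels and selects pixels falling inside all
three windows.  Staining area is the selected pixel count × pixel area,
optionally restricted to a polygon ROI and minus an artefact-exclusion
mask.  For comparative validity a single threshold, calibrated once by
eye on strong and weak stainings, is applied unchanged to every image of
a batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    CalibratedImage,
    PolygonROI,
    RegionMask,
    UnsupportedImageError,
    polygon_to_mask,
    write_image,
)

__all__ = [
    "RGBThreshold",
    "StainQuantResult",
    "apply_rgb_threshold",
    "quantify_stain_area",
    "preview_threshold",
]


@dataclass(frozen=True)
class RGBThreshold:
    """Per-channel inclusive intensity windows defining the stain colour class."""

    r_min: int
    r_max: int
    g_min: int
    g_max: int
    b_min: int
    b_max: int

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.r_min, self.r_max, "red"),
            (self.g_min, self.g_max, "green"),
            (self.b_min, self.b_max, "blue"),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} window [{lo}, {hi}] invalid: need 0 <= min <= max <= 255")

    @classmethod
    def parse(cls, text: str) -> "RGBThreshold":
        """Parse ``r_min,r_max,g_min,g_max,b_min,b_max``."""
        vals = [int(v) for v in text.split(",")]
        if len(vals) != 6:
            raise ValueError("threshold needs 6 comma-separated integers")
        return cls(*vals)


@dataclass(frozen=True)
class StainQuantResult:
    image_id: str
    selected_pixels: int
    area_um2: float
    threshold: RGBThreshold
    roi_applied: bool
    exclusion_applied: bool


def apply_rgb_threshold(image: CalibratedImage, t: RGBThreshold) -> RegionMask:
    """Select pixels inside all three channel windows (bounds inclusive)."""
    if not image.is_rgb:
        raise UnsupportedImageError(
            "RGB thresholding needs a 3-channel image; convert grayscale upstream"
        )
    px = image.pixels
    mask = (
        (px[:, :, 0] >= t.r_min)
        & (px[:, :, 0] <= t.r_max)
        & (px[:, :, 1] >= t.g_min)
        & (px[:, :, 1] <= t.g_max)
        & (px[:, :, 2] >= t.b_min)
        & (px[:, :, 2] <= t.b_max)
    )
    return RegionMask(mask=mask, calibration=image.calibration)


def quantify_stain_area(
    image: CalibratedImage,
    t: RGBThreshold,
    roi: PolygonROI | None = None,
    exclude: RegionMask | None = None,
    image_id: str = "",
) -> StainQuantResult:
    """Staining area over (threshold ∩ ROI) minus the exclusion mask."""
    mask = apply_rgb_threshold(image, t).mask
    if roi is not None:
        roi_mask = polygon_to_mask(roi, image).mask
        if not roi_mask.any():
            raise ValueError("ROI covers no pixels of the image")
        mask = mask & roi_mask
    if exclude is not None:
        if exclude.mask.shape != image.shape:
            raise ValueError("exclusion mask does not align with the image")
        mask = mask & ~exclude.mask
    n = int(mask.sum())
    return StainQuantResult(
        image_id=image_id,
        selected_pixels=n,
        area_um2=n * image.calibration.area_factor,
        threshold=t,
        roi_applied=roi is not None,
        exclusion_applied=exclude is not None,
    )


def preview_threshold(
    image: CalibratedImage,
    t: RGBThreshold,
    out: str | Path,
    highlight: tuple[int, int, int] = (255, 0, 255),
) -> RegionMask:
    """Write the image with threshold-selected pixels painted, for the
    visual trial-and-error calibration of the threshold."""
    mask = apply_rgb_threshold(image, t)
    overlay = image.pixels.copy()
    overlay[mask.mask] = highlight
    write_image(out, CalibratedImage(overlay, image.calibration))
    return mask
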