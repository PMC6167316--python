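"""Shared data model for calibrated-image quantification.

Coordinate convention: images are oriented anterior-left, dorsal-up.
Pixel indices are 0-based with the origin at the top-left corner; ``x``
(column) increases posteriorly (rightward) and ``y`` (row) increases
ventrally (downward).  Pixel ``(i, j)`` covers the square
``[i, i+1) x [j, j+1)``, so its centre sits at ``(i + 0.5, j + 0.5)``.
All physical quantities are reported in micrometres (μm) or μm², using a
single isotropic pixel size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger("tailquant")

__all__ = [
    "TailquantError",
    "MissingCalibrationError",
    "UnsupportedImageError",
    "DetectionFailureError",
    "PixelCalibration",
    "CalibratedImage",
    "Point2D",
    "RegionMask",
    "PolygonROI",
    "ResultTable",
    "read_image",
    "write_image",
    "polygon_area",
    "polygon_to_mask",
    "read_landmarks",
    "read_polygon",
    "write_landmarks",
]


class TailquantError(Exception):
    """Base class for all package errors."""


class MissingCalibrationError(TailquantError):
    """No pixel size available from metadata or override."""


class UnsupportedImageError(TailquantError):
    """Image format, bit depth or channel layout not supported."""


class DetectionFailureError(TailquantError):
    """An automatic detection step found nothing usable."""


@dataclass(frozen=True)
class PixelCalibration:
    """Isotropic pixel size in μm per pixel."""

    pixel_size_um: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(
                f"pixel_size_um must be positive and finite, got {self.pixel_size_um!r}"
            )

    @property
    def area_factor(self) -> float:
        """μm² per pixel."""
        return self.pixel_size_um**2


@dataclass
class CalibratedImage:
    """2-D raster (grayscale 8/16-bit or 8-bit RGB) with physical calibration.

    The orientation tag records the assumed anatomical axes; every sign
    convention downstream (e.g. posterior = larger x) relies on it.
    """

    pixels: np.ndarray
    calibration: PixelCalibration
    orientation: str = "anterior-left"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            pass
        elif px.ndim == 3 and px.shape[2] == 3:
            if px.dtype != np.uint8:
                raise UnsupportedImageError(
                    f"RGB images must be 8-bit per channel, got dtype {px.dtype}"
                )
        else:
            raise UnsupportedImageError(
                f"expected a 2-D grayscale or HxWx3 RGB raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise UnsupportedImageError("image must be at least 1x1")
        self.pixels = px

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def pixel_size_um(self) -> float:
        return self.calibration.pixel_size_um


@dataclass(frozen=True)
class Point2D:
    """Sub-pixel 2-D point in pixel units (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class RegionMask:
    """Boolean raster aligned to a CalibratedImage."""

    mask: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")
        self.mask = m

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.calibration.area_factor

    def aligned_with(self, image: CalibratedImage) -> bool:
        return self.mask.shape == image.shape


@dataclass
class PolygonROI:
    """Closed simple polygon given as an ordered vertex list (pixel units)."""

    vertices: Sequence[Point2D]

    def __post_init__(self) -> None:
        verts = list(self.vertices)
        if len(verts) < 3:
            raise ValueError(f"a polygon needs at least 3 vertices, got {len(verts)}")
        pts = np.array([(p.x, p.y) for p in verts])
        x, y = pts[:, 0], pts[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        # zero-area (collinear/degenerate) polygons are accepted; area ops warn
        if shoelace > 0 and not _ShapelyPolygon(pts).is_valid:
            raise ValueError("polygon is self-intersecting; only simple polygons are supported")
        self.vertices = verts

    def as_array(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.vertices], dtype=float)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon([(p.x, p.y) for p in self.vertices])


class ResultTable:
    """Tidy measurement table: one row per (image, measurement).

    Thin wrapper over a DataFrame with fixed columns
    ``image_id, measurement, value, units`` — the CSV the pipeline exports
    for downstream statistics.
    """

    COLUMNS = ("image_id", "measurement", "value", "units")

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"result table missing columns: {sorted(missing)}")
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)

    def add(self, image_id: str, measurement: str, value: float, units: str) -> None:
        if not units:
            raise ValueError("units must be non-empty")
        dup = (self.df["image_id"] == image_id) & (self.df["measurement"] == measurement)
        if dup.any():
            raise ValueError(
                f"duplicate measurement {measurement!r} for image {image_id!r}"
            )
        self.df.loc[len(self.df)] = [image_id, measurement, float(value), units]

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResultTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Image I/O


def _pixel_size_from_tiff(page: "tifffile.TiffPage") -> float | None:
    """Extract μm/pixel from TIFF resolution metadata, if present.

    Resolutions are stored as pixels-per-unit.  ImageJ-style files carry the
    unit in their metadata; plain TIFFs use the ResolutionUnit tag
    (2 = inch, 3 = cm).  With no unit tag the resolution is taken as
    pixels per μm, which is how this package writes its own files.
    """
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    px_per_unit_x = num / den
    if yres is not None:
        ynum, yden = yres.value
        if ynum != 0:
            px_per_unit_y = ynum / yden
            if not math.isclose(px_per_unit_x, px_per_unit_y, rel_tol=1e-6):
                raise UnsupportedImageError(
                    "anisotropic pixels (XResolution != YResolution) are not supported"
                )
    unit_to_um = 1.0  # default: resolution already in px/μm
    resunit = tags.get("ResolutionUnit")
    if resunit is not None and getattr(resunit.value, "value", resunit.value) == 2:
        unit_to_um = 25400.0  # inch
    elif resunit is not None and getattr(resunit.value, "value", resunit.value) == 3:
        unit_to_um = 10000.0  # cm
    return unit_to_um / px_per_unit_x


def read_image(
    path: str | Path, calibration_override: PixelCalibration | None = None
) -> CalibratedImage:
    """Read a TIFF or PNG image with its physical calibration.

    TIFF resolution metadata takes precedence; otherwise the override is
    used.  Raises :class:`MissingCalibrationError` when neither is
    available.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    calibration: PixelCalibration | None = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            px_um = _pixel_size_from_tiff(page)
            if px_um is not None:
                calibration = PixelCalibration(px_um)
    elif suffix == ".png":
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 3 and pixels.shape[2] == 4:
            pixels = pixels[:, :, :3]
    else:
        raise UnsupportedImageError(f"unsupported image format: {path.name}")
    if calibration is None:
        calibration = calibration_override
    if calibration is None:
        raise MissingCalibrationError(
            f"{path.name}: no pixel size in metadata and no override provided"
        )
    if pixels.dtype not in (np.uint8, np.uint16):
        raise UnsupportedImageError(
            f"{path.name}: unsupported bit depth {pixels.dtype}; expected 8- or 16-bit"
        )
    return CalibratedImage(pixels=pixels, calibration=calibration)


def write_image(path: str | Path, image: CalibratedImage) -> None:
    """Write a calibrated image.

    TIFF output stores the calibration as X/YResolution in pixels per μm,
    which :func:`read_image` round-trips bit-exactly.  PNG output drops the
    calibration (the format has no standard μm unit).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        px_per_um = 1.0 / image.pixel_size_um
        tifffile.imwrite(
            path,
            image.pixels,
            photometric="rgb" if image.is_rgb else "minisblack",
            resolution=(px_per_um, px_per_um),
            resolutionunit="NONE",  # unit-less: px per μm by package convention
        )
    elif suffix == ".png":
        iio.imwrite(path, image.pixels)
    else:
        raise UnsupportedImageError(f"unsupported output format: {path.name}")


# ---------------------------------------------------------------------------
# Polygon geometry


def polygon_area(roi: PolygonROI, calibration: PixelCalibration) -> float:
    """Polygon area in μm² by the shoelace formula (orientation-independent)."""
    pts = roi.as_array()
    x, y = pts[:, 0], pts[:, 1]
    area_px = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area_px == 0.0:
        warnings.warn("degenerate polygon with zero area", stacklevel=2)
        return 0.0
    return float(area_px * calibration.area_factor)


def polygon_to_mask(roi: PolygonROI, image: CalibratedImage) -> RegionMask:
    """Rasterise a polygon: a pixel is included iff its centre lies inside.

    Polygons extending beyond the image are clipped with a warning.
    """
    h, w = image.shape
    poly = roi.to_shapely()
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        warnings.warn("polygon extends beyond image bounds; clipping", stacklevel=2)
    mask = np.zeros((h, w), dtype=bool)
    i0 = max(int(math.floor(minx)), 0)
    i1 = min(int(math.ceil(maxx)), w)
    j0 = max(int(math.floor(miny)), 0)
    j1 = min(int(math.ceil(maxy)), h)
    if i1 > i0 and j1 > j0:
        xs = np.arange(i0, i1) + 0.5
        ys = np.arange(j0, j1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        mask[j0:j1, i0:i1] = inside
    return RegionMask(mask=mask, calibration=image.calibration)


# ---------------------------------------------------------------------------
# Landmark / ROI CSV I/O  (header: name,x,y ; pixel units)


def read_landmarks(path: str | Path) -> dict[str, Point2D]:
    """Read a named landmark CSV; each name must appear exactly once."""
    df = pd.read_csv(path)
    _check_landmark_columns(df, path)
    dup = df["name"][df["name"].duplicated()]
    if len(dup):
        raise ValueError(
            f"{path}: duplicated landmark names {sorted(set(dup))}; "
            "use read_polygon for multi-point ROIs"
        )
    return {str(r["name"]): Point2D(float(r["x"]), float(r["y"])) for _, r in df.iterrows()}


def read_polygon(path: str | Path, name: str | None = None) -> PolygonROI:
    """Read a polygon ROI from a landmark CSV (ordered rows sharing a name)."""
    df = pd.read_csv(path)
    _check_landmark_columns(df, path)
    if name is not None:
        df = df[df["name"] == name]
        if df.empty:
            raise ValueError(f"{path}: no rows named {name!r}")
    elif df["name"].nunique() > 1:
        raise ValueError(
            f"{path}: multiple ROI names present ({sorted(df['name'].unique())}); pass name="
        )
    return PolygonROI([Point2D(float(x), float(y)) for x, y in zip(df["x"], df["y"])])


def write_landmarks(path: str | Path, landmarks: dict[str, Point2D]) -> None:
    pd.DataFrame(
        [{"name": n, "x": p.x, "y": p.y} for n, p in landmarks.items()]
    ).to_csv(path, index=False)


def _check_landmark_columns(df: pd.DataFrame, path) -> None:
    missing = {"name", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: landmark CSV missing columns {sorted(missing)}")
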