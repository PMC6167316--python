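"""Ground-truthed synthetic fixtures for every stage of the pipeline.

Each generator emulates one image class the pipeline measures — a wounded
larva with a fluorescent wound band, chromogenic stain blobs, notochord
membrane arcs, pre/post contraction landmark sets, mitotic spots — and
records every scene parameter in a machine-readable manifest so the
downstream measurement can be predicted analytically (exactly, when the
noise level is zero).

Determinism: the same seed and parameters reproduce outputs bit-exactly.
Disks are rasterised by pixel-centre inclusion and the manifest records
the rasterised pixel count, not the analytic area, so area assertions in
tests are exact.  The default calibration is 1 μm/px so physical and
pixel units coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CalibratedImage, PixelCalibration, Point2D
from .morphometry import MembraneTriple

__all__ = [
    "GroundTruthManifest",
    "WoundSceneParams",
    "ContractionParams",
    "StainBlob",
    "SpotSpec",
    "CONTRACTION_PRESETS",
    "gen_wound_embryo",
    "gen_stain_image",
    "gen_membrane_triples",
    "gen_contraction_pair",
    "gen_spot_image",
]

DEFAULT_CALIBRATION = PixelCalibration(1.0)

#: Group-mean axial trunk contraction (%) measured 2 h after tail excision:
#: untreated larvae contract by 4.4% on average, larvae treated with the
#: NADPH-oxidase inhibitor DPI by 1.7% and with the Src-family-kinase
#: inhibitor PP2 by 1.2%.  Used as ground-truth presets for recovery tests.
CONTRACTION_PRESETS: dict[str, float] = {
    "untreated": 4.4,
    "dpi": 1.7,
    "pp2": 1.2,
}


class GroundTruthManifest:
    """Record of every parameter used to synthesise fixtures.

    One entry per generated fixture; serialisable to JSON for
    parameter-recovery tests and CLI runs.
    """

    def __init__(self, entries: list[dict] | None = None):
        self.entries: list[dict] = entries or []

    def add(self, entry: dict) -> dict:
        self.entries.append(entry)
        return entry

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Wound / ROS scene


@dataclass
class WoundSceneParams:
    """Scene for the wound-fluorescence quantification fixture.

    The embryo silhouette is an ellipse body continued by a tapering tail
    band, truncated at ``wound_x_px`` to model the amputation stump
    (anterior left, so the wound is the posterior-most extent).  The
    fluorescence channel is ``basal_intensity`` inside the embryo and
    ``band_intensity`` within ``band_width_um`` of the wound plane, plus
    optional Gaussian noise.
    """

    band_intensity: float = 200.0
    basal_intensity: float = 50.0
    band_width_um: float = 50.0
    edge_window_um: float = 25.0  # matches the quantifier's wound-edge arc window
    noise_sigma: float = 0.0
    image_shape: tuple[int, int] = (256, 1400)  # (rows, cols)
    wound_x_px: int = 1250
    calibration: PixelCalibration = DEFAULT_CALIBRATION

    def __post_init__(self) -> None:
        if not (self.band_intensity >= self.basal_intensity >= 0):
            raise ValueError("require band_intensity >= basal_intensity >= 0")
        if self.band_width_um <= 0:
            raise ValueError("band_width_um must be positive")


def _embryo_silhouette(shape: tuple[int, int], wound_x: int) -> np.ndarray:
    """Ellipse body + tapering tail, truncated at the wound plane."""
    h, w = shape
    cy = h // 2
    cx, ax, ay = 300, 280, min(100, cy - 10)
    yy, xx = np.mgrid[0:h, 0:w]
    body = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    tail_end = w - 20
    frac = np.clip((xx - cx) / max(tail_end - cx, 1), 0.0, 1.0)
    half_h = 0.7 * ay * (1 - frac) + 28 * frac
    tail = (xx >= cx) & (xx <= tail_end) & (np.abs(yy - cy) <= half_h)
    mask = body | tail
    mask[:, wound_x:] = False
    return mask


def gen_wound_embryo(
    params: WoundSceneParams, seed: int | None = 0
) -> tuple[CalibratedImage, CalibratedImage, dict]:
    """Generate a (brightfield, fluorescence) pair with a wound band.

    The brightfield channel shows a dark embryo on a light background for
    outline detection.  The elevated-fluorescence region is defined by
    horizontal distance to the wound plane (the vertical cut at the
    stump) and extends ``band_width_um + edge_window_um`` from it.  The
    quantifier's wound band — geodesic distance at most ``band_width_um``
    from an edge arc that reaches ``edge_window_um`` along the boundary —
    is a subset of this region (geodesic distance bounds horizontal
    distance), so the noiseless wound-band mean is exactly
    ``band_intensity`` and the truth score is ``band_intensity -
    basal_intensity``.
    """
    rng = np.random.default_rng(seed)
    px = params.calibration.pixel_size_um
    mask = _embryo_silhouette(params.image_shape, params.wound_x_px)
    if not mask.any():
        raise ValueError("empty embryo silhouette")
    xs = np.where(mask.any(axis=0))[0]
    embryo_len_um = (xs.max() - xs.min() + 1) * px
    if params.band_width_um >= embryo_len_um:
        raise ValueError(
            f"band width {params.band_width_um} μm exceeds embryo length {embryo_len_um} μm"
        )

    bright = np.full(params.image_shape, 220.0)
    bright[mask] = 60.0
    bright += rng.normal(0.0, 3.0, size=bright.shape)
    bright_img = CalibratedImage(
        np.clip(np.rint(bright), 0, 255).astype(np.uint8), params.calibration
    )

    h, w = params.image_shape
    xx = np.arange(w)[None, :].repeat(h, axis=0)
    wound_edge_x = xs.max()  # last embryo column before the cut
    dist_to_wound_um = (wound_edge_x - xx) * px
    band = mask & (dist_to_wound_um <= params.band_width_um + params.edge_window_um)
    fluor = np.zeros(params.image_shape, dtype=float)
    fluor[mask] = params.basal_intensity
    fluor[band] = params.band_intensity
    if params.noise_sigma > 0:
        fluor += rng.normal(0.0, params.noise_sigma, size=fluor.shape)
    fluor_img = CalibratedImage(
        np.clip(np.rint(fluor), 0, 255).astype(np.uint8), params.calibration
    )

    entry = {
        "generator": "gen_wound_embryo",
        "seed": seed,
        "calibration_um": px,
        "params": {
            "band_intensity": params.band_intensity,
            "basal_intensity": params.basal_intensity,
            "band_width_um": params.band_width_um,
            "edge_window_um": params.edge_window_um,
            "noise_sigma": params.noise_sigma,
            "image_shape": list(params.image_shape),
            "wound_x_px": params.wound_x_px,
        },
        "truth": {
            "score": params.band_intensity - params.basal_intensity,
            "silhouette_area_um2": float(mask.sum()) * params.calibration.area_factor,
            "wound_edge_x_px": int(wound_edge_x),
            "band_pixels": int(band.sum()),
        },
    }
    return bright_img, fluor_img, entry


# ---------------------------------------------------------------------------
# Exact-area disk rasterisation (shared by stain and spot scenes)


def _rasterise_disk_exact(
    shape: tuple[int, int], centre: tuple[float, float], n_pixels: int
) -> np.ndarray:
    """Boolean disk containing exactly ``n_pixels`` pixel centres.

    Selects the ``n_pixels`` pixel centres nearest ``centre``; the implied
    radius lies strictly between the n-th and (n+1)-th nearest-centre
    distances, so the region is a true pixel-centre-rasterised disk.
    Centres on a slightly irrational sub-pixel offset avoid distance ties.
    """
    h, w = shape
    cx, cy = centre
    r_max = int(np.ceil(np.sqrt(n_pixels / np.pi))) + 3
    i0, i1 = max(int(cx) - r_max, 0), min(int(cx) + r_max + 1, w)
    j0, j1 = max(int(cy) - r_max, 0), min(int(cy) + r_max + 1, h)
    xs = np.arange(i0, i1) + 0.5
    ys = np.arange(j0, j1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx - cx) ** 2 + (gy - cy) ** 2
    flat = np.sort(d2.ravel())
    if n_pixels >= flat.size:
        raise ValueError("disk does not fit in the image")
    if flat[n_pixels - 1] == flat[n_pixels]:
        raise ValueError(
            "distance tie prevents an exact-area disk; offset the centre sub-pixel"
        )
    thresh = 0.5 * (flat[n_pixels - 1] + flat[n_pixels])
    mask = np.zeros(shape, dtype=bool)
    mask[j0:j1, i0:i1] = d2 <= thresh
    return mask


_TIE_BREAK_OFFSET = (0.31830989, 0.36787944)  # 1/π, 1/e — avoids centre ties


# ---------------------------------------------------------------------------
# Chromogenic stain scene


@dataclass
class StainBlob:
    """One stain blob: RGB colour, target area and centre (pixel units)."""

    color: tuple[int, int, int]
    area_um2: float
    centre: Point2D
    artefact: bool = False  # e.g. a bubble — flagged for exclusion tests


def gen_stain_image(
    blobs: Sequence[StainBlob],
    background: tuple[int, int, int] = (235, 224, 205),
    calibration: PixelCalibration = DEFAULT_CALIBRATION,
    seed: int | None = 0,
    image_shape: tuple[int, int] = (400, 400),
    noise_sigma: float = 0.0,
) -> tuple[CalibratedImage, dict]:
    """Render disjoint stain disks of known pixel area on a tissue background.

    The manifest records each blob's exact rasterised pixel count and its
    artefact flag, so threshold-based area quantification can be checked
    exactly (with noise_sigma = 0) and artefact-exclusion masks can be
    verified against ground truth.
    """
    rng = np.random.default_rng(seed)
    px = calibration.pixel_size_um
    for b in blobs:
        if tuple(b.color) == tuple(background):
            raise ValueError("blob colour must differ from the background")
    masks = []
    for b in blobs:
        n = int(round(b.area_um2 / calibration.area_factor))
        if n < 1:
            raise ValueError(f"blob area {b.area_um2} μm² is below one pixel")
        centre = (b.centre.x + _TIE_BREAK_OFFSET[0], b.centre.y + _TIE_BREAK_OFFSET[1])
        masks.append(_rasterise_disk_exact(image_shape, centre, n))
    union = np.zeros(image_shape, dtype=bool)
    for m in masks:
        if (union & m).any():
            raise ValueError("stain blobs overlap; blobs must be disjoint")
        union |= m

    img = np.empty((*image_shape, 3), dtype=float)
    img[:] = background
    for b, m in zip(blobs, masks):
        img[m] = b.color
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    image = CalibratedImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), calibration)

    entry = {
        "generator": "gen_stain_image",
        "seed": seed,
        "calibration_um": px,
        "params": {
            "background": list(background),
            "noise_sigma": noise_sigma,
            "image_shape": list(image_shape),
        },
        "blobs": [
            {
                "color": list(b.color),
                "centre": [b.centre.x, b.centre.y],
                "pixels": int(m.sum()),
                "area_um2": float(m.sum()) * calibration.area_factor,
                "artefact": b.artefact,
            }
            for b, m in zip(blobs, masks)
        ],
        "truth": {
            "stain_area_um2": float(
                sum(int(m.sum()) for b, m in zip(blobs, masks) if not b.artefact)
            )
            * calibration.area_factor
        },
    }
    return image, entry


# ---------------------------------------------------------------------------
# Membrane curvature triples


def gen_membrane_triples(
    radii: Sequence[tuple[float, str]],
    chord_span_um: float = 40.0,
    calibration: PixelCalibration = DEFAULT_CALIBRATION,
    seed: int | None = 0,
    centre: Point2D = Point2D(300.0, 150.0),
) -> tuple[list[MembraneTriple], dict]:
    """Construct membrane triples exactly on circles of known radius.

    ``radii`` is a list of ``(R_um, bow)`` with bow one of ``"posterior"``
    (truth κ = +1/R), ``"anterior"`` (−1/R) or ``"straight"`` (κ = 0).
    The two sheath contacts sit on a near-vertical chord of the stated
    span; the apex is the circle point furthest from the chord, on the
    bowed side.  Contact angles get a small random asymmetry so the three
    points are generic while remaining exactly on the circle.
    """
    rng = np.random.default_rng(seed)
    px = calibration.pixel_size_um
    triples: list[MembraneTriple] = []
    truths: list[dict] = []
    for r_um, bow in radii:
        if bow == "straight":
            half = chord_span_um / (2 * px)
            a = Point2D(centre.x, centre.y - half)
            b = Point2D(centre.x, centre.y + half)
            apex = Point2D(centre.x, centre.y + half * float(rng.uniform(-0.8, 0.8)))
            kappa_true = 0.0
        else:
            if r_um <= 0:
                raise ValueError("radius must be positive for curved membranes")
            r_px = r_um / px
            half_span = chord_span_um / (2 * px)
            if half_span >= r_px:
                raise ValueError("chord span exceeds circle diameter")
            # apex direction: +x for posterior bow, -x for anterior
            s = 1.0 if bow == "posterior" else -1.0
            if bow not in ("posterior", "anterior"):
                raise ValueError(f"unknown bow direction {bow!r}")
            c = np.array([centre.x - s * (r_px - 1.0), centre.y])
            phi = np.arcsin(half_span / r_px)
            eps = float(rng.uniform(-0.1, 0.1)) * phi
            a_ang, b_ang = -phi + eps, phi + eps
            a = Point2D(c[0] + s * r_px * np.cos(a_ang), c[1] + r_px * np.sin(a_ang))
            b = Point2D(c[0] + s * r_px * np.cos(b_ang), c[1] + r_px * np.sin(b_ang))
            # apex at the chord's mid-angle: the circle point furthest from it
            apex = Point2D(c[0] + s * r_px * np.cos(eps), c[1] + r_px * np.sin(eps))
            kappa_true = s / r_um
        triples.append(MembraneTriple(sheath_a=a, sheath_b=b, apex=apex, calibration=calibration))
        truths.append({"R_um": r_um, "bow": bow, "kappa_um_inv": kappa_true})
    entry = {
        "generator": "gen_membrane_triples",
        "seed": seed,
        "calibration_um": px,
        "params": {"chord_span_um": chord_span_um},
        "truth": truths,
    }
    return triples, entry


# ---------------------------------------------------------------------------
# Trunk contraction landmark pairs


@dataclass
class ContractionParams:
    """Pre/post landmark scene for trunk-contraction recovery.

    Landmarks are somite-boundary proxies spaced evenly along the body
    axis over ``span_um`` (about eight somites).  The post set is the pre
    set scaled by ``1 - c/100`` along the axis, plus Gaussian placement
    jitter on each coordinate (hand-placement error).
    """

    true_contraction_percent: float = CONTRACTION_PRESETS["untreated"]
    n_landmarks: int = 8
    span_um: float = 800.0
    jitter_sigma_um: float = 0.0
    axis: tuple[float, float] = (1.0, 0.0)
    origin: Point2D = Point2D(100.0, 150.0)
    calibration: PixelCalibration = DEFAULT_CALIBRATION

    def __post_init__(self) -> None:
        if not (0 <= self.true_contraction_percent < 100):
            raise ValueError("contraction must be in [0, 100)%")
        if self.n_landmarks < 2:
            raise ValueError("need at least two landmarks")


def gen_contraction_pair(
    params: ContractionParams, seed: int | None = 0
) -> tuple[dict[str, Point2D], dict[str, Point2D], dict]:
    """Generate matched pre/post landmark sets with known axial contraction.

    Returns ``(pre, post, manifest_entry)`` where landmarks are named
    ``s0 .. s{n-1}`` from anterior to posterior.  With zero jitter, the
    span measured between ``s0`` and ``s{n-1}`` recovers the configured
    contraction exactly.
    """
    rng = np.random.default_rng(seed)
    px = params.calibration.pixel_size_um
    axis = np.asarray(params.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = params.origin.as_array()
    offsets_um = np.linspace(0.0, params.span_um, params.n_landmarks)
    pre_pts = origin[None, :] + (offsets_um[:, None] / px) * axis[None, :]
    scale = 1.0 - params.true_contraction_percent / 100.0
    post_pts = origin[None, :] + (offsets_um[:, None] * scale / px) * axis[None, :]
    if params.jitter_sigma_um > 0:
        post_pts = post_pts + rng.normal(
            0.0, params.jitter_sigma_um / px, size=post_pts.shape
        )
    names = [f"s{i}" for i in range(params.n_landmarks)]
    pre = {n: Point2D(*p) for n, p in zip(names, pre_pts)}
    post = {n: Point2D(*p) for n, p in zip(names, post_pts)}
    entry = {
        "generator": "gen_contraction_pair",
        "seed": seed,
        "calibration_um": px,
        "params": {
            "true_contraction_percent": params.true_contraction_percent,
            "n_landmarks": params.n_landmarks,
            "span_um": params.span_um,
            "jitter_sigma_um": params.jitter_sigma_um,
            "axis": list(map(float, axis)),
        },
        "truth": {"contraction_percent": params.true_contraction_percent},
    }
    return pre, post, entry


# ---------------------------------------------------------------------------
# Mitotic-spot scene


@dataclass
class SpotSpec:
    """One mitotic spot: target area and centroid distance from the caudal point."""

    area_um2: float
    distance_um: float
    angle_deg: float | None = None  # bearing from the caudal point; random if None


def gen_spot_image(
    spots: Sequence[SpotSpec],
    caudal_point: Point2D = Point2D(700.0, 400.0),
    calibration: PixelCalibration = DEFAULT_CALIBRATION,
    seed: int | None = 0,
    image_shape: tuple[int, int] = (800, 1400),
    intensity: int = 200,
    noise_sigma: float = 0.0,
    min_area_um2: float = 50.0,
    max_dist_um: float = 500.0,
) -> tuple[CalibratedImage, dict]:
    """Render bright disks at known areas and distances from a caudal point.

    The manifest records each spot's exact rasterised pixel area, its
    rasterised centroid distance to the caudal point, and whether it
    passes the counting filters (area strictly greater than
    ``min_area_um2``, distance at most ``max_dist_um``), so the expected
    count is available as ground truth.
    """
    rng = np.random.default_rng(seed)
    px = calibration.pixel_size_um
    h, w = image_shape
    masks, records = [], []
    union = np.zeros(image_shape, dtype=bool)
    for s in spots:
        n = int(round(s.area_um2 / calibration.area_factor))
        if n < 1:
            raise ValueError(f"spot area {s.area_um2} μm² is below one pixel")
        ang = np.deg2rad(s.angle_deg if s.angle_deg is not None else rng.uniform(0, 360))
        cx = caudal_point.x + (s.distance_um / px) * np.cos(ang) + _TIE_BREAK_OFFSET[0]
        cy = caudal_point.y + (s.distance_um / px) * np.sin(ang) + _TIE_BREAK_OFFSET[1]
        r_est = np.sqrt(n / np.pi) + 3
        if not (r_est <= cx <= w - r_est and r_est <= cy <= h - r_est):
            raise ValueError(
                f"spot at distance {s.distance_um} μm, bearing {np.rad2deg(ang):.0f}° "
                "does not fit in the image; pick an explicit angle"
            )
        m = _rasterise_disk_exact(image_shape, (cx, cy), n)
        if (union & m).any():
            raise ValueError("spots overlap; choose different angles/distances")
        union |= m
        masks.append(m)
        jj, ii = np.nonzero(m)
        centroid = (ii.mean() + 0.5, jj.mean() + 0.5)
        dist_um = (
            np.hypot(centroid[0] - caudal_point.x, centroid[1] - caudal_point.y) * px
        )
        area = int(m.sum()) * calibration.area_factor
        records.append(
            {
                "pixels": int(m.sum()),
                "area_um2": area,
                "centroid": [centroid[0], centroid[1]],
                "distance_um": float(dist_um),
                "passes": bool(area > min_area_um2 and dist_um <= max_dist_um),
            }
        )

    img = np.zeros(image_shape, dtype=float)
    img[union] = intensity
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    image = CalibratedImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), calibration)
    entry = {
        "generator": "gen_spot_image",
        "seed": seed,
        "calibration_um": px,
        "params": {
            "caudal_point": [caudal_point.x, caudal_point.y],
            "image_shape": list(image_shape),
            "intensity": intensity,
            "noise_sigma": noise_sigma,
            "min_area_um2": min_area_um2,
            "max_dist_um": max_dist_um,
        },
        "spots": records,
        "truth": {"expected_count": sum(r["passes"] for r in records)},
    }
    return image, entry
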