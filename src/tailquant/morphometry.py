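"""Geometric measurements on the regenerating larval tail.

Covers the signed Menger curvature of notochord cell membranes, axial
trunk-contraction measurement between named landmarks, tail-length /
regrowth distances measured parallel to the body axis, and notochord-bead
area from a polygon ROI.

Curvature sign convention (anterior-left images): a membrane bowed toward
the posterior (apex at larger x than its chord) has positive curvature,
one bowed anterior negative, and a straight membrane perpendicular to the
notochord sheath has curvature exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PixelCalibration, Point2D, PolygonROI, polygon_area

__all__ = [
    "MembraneTriple",
    "CurvatureResult",
    "AxisSegment",
    "ContractionResult",
    "MembraneTrace",
    "menger_curvature",
    "measure_axial_length",
    "measure_contraction",
    "bead_area",
    "select_measurement_cell",
]

#: Below this normalised triangle "sine" (2·area / product of the two apex
#: side lengths) the three points are treated as collinear and κ = 0.
COLLINEARITY_TOL = 1e-9


@dataclass(frozen=True)
class MembraneTriple:
    """Two sheath-contact points and the membrane apex, in pixel units.

    The apex is the membrane point furthest from the chord through the two
    points where the cell contacts the notochord sheath; the circle
    through the three points approximates the membrane arc.
    """

    sheath_a: Point2D
    sheath_b: Point2D
    apex: Point2D
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        pts = [self.sheath_a, self.sheath_b, self.apex]
        for i in range(3):
            for j in range(i + 1, 3):
                if pts[i].x == pts[j].x and pts[i].y == pts[j].y:
                    raise ValueError("membrane triple has coincident points")


@dataclass(frozen=True)
class CurvatureResult:
    """Signed Menger curvature κ = sign / R of a membrane triple."""

    kappa: float  # μm⁻¹, signed
    radius_um: float  # 1/|κ|; inf when κ = 0
    sign: int  # +1 posterior bow, −1 anterior, 0 straight


def menger_curvature(triple: MembraneTriple) -> CurvatureResult:
    """Signed Menger curvature of the circle through three membrane points.

    The magnitude is ``4A / (a·b·c)`` with ``A`` the triangle area and
    ``a, b, c`` its side lengths in μm — the inverse circumcircle radius.
    The sign is taken from the apex's side of the chord: positive when the
    apex lies posterior (larger x) to its perpendicular foot on the chord,
    negative when anterior.  This equals the circumcentre convention
    (centre and apex fall on opposite sides of the chord) but stays
    numerically stable as the membrane straightens.  A chord running
    exactly parallel to the body axis has no anterior/posterior
    laterality; the degenerate zero offset is resolved as positive.
    """
    px = triple.calibration.pixel_size_um
    pa = triple.sheath_a.as_array() * px
    pb = triple.sheath_b.as_array() * px
    ap = triple.apex.as_array() * px

    u = pa - ap
    v = pb - ap
    cross = u[0] * v[1] - u[1] * v[0]
    area2 = abs(cross)  # = 2A
    sine = area2 / (np.linalg.norm(u) * np.linalg.norm(v))
    if sine < COLLINEARITY_TOL:
        return CurvatureResult(kappa=0.0, radius_um=math.inf, sign=0)

    a = np.linalg.norm(pb - ap)
    b = np.linalg.norm(pa - ap)
    c = np.linalg.norm(pb - pa)
    kappa_abs = 2.0 * area2 / (a * b * c)  # 4A/(abc)

    # apex laterality: x-offset of the apex from its foot on the chord
    chord = pb - pa
    t = np.dot(ap - pa, chord) / np.dot(chord, chord)
    foot = pa + t * chord
    sign = 1 if math.copysign(1.0, ap[0] - foot[0]) > 0 else -1
    return CurvatureResult(kappa=sign * kappa_abs, radius_um=1.0 / kappa_abs, sign=sign)


@dataclass(frozen=True)
class AxisSegment:
    """A start/end point pair measured along a body-axis direction."""

    start: Point2D
    end: Point2D
    axis: tuple[float, float]
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        norm = math.hypot(*self.axis)
        if norm == 0:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))


def measure_axial_length(segment: AxisSegment) -> float:
    """Length of the segment projected onto the axis, in μm.

    Mirrors measuring with a rectangle laid parallel to the body: only the
    along-axis component of the displacement counts, so perpendicular
    displacement of either endpoint leaves the length unchanged.
    """
    d = segment.end.as_array() - segment.start.as_array()
    proj = abs(d[0] * segment.axis[0] + d[1] * segment.axis[1])
    return float(proj * segment.calibration.pixel_size_um)


@dataclass(frozen=True)
class ContractionResult:
    """Axial trunk shortening between two imaging time points."""

    L_pre_um: float
    L_post_um: float
    contraction_percent: float


def measure_contraction(
    pre: dict[str, Point2D],
    post: dict[str, Point2D],
    axis: tuple[float, float],
    calibration: PixelCalibration,
    landmarks: tuple[str, str] | None = None,
) -> ContractionResult:
    """Percent axial shortening between two named landmarks.

    The span between the first and last somite-boundary reference
    landmarks is measured parallel to the notochord axis in both the
    pre-excision and 2 h post-excision landmark sets;
    ``contraction = 100 · (L_pre − L_post) / L_pre``.

    ``landmarks`` names the anterior and posterior reference; by default
    the landmarks common to both sets that are extreme along the axis in
    the pre set are used.
    """
    if landmarks is None:
        common = sorted(set(pre) & set(post))
        if len(common) < 2:
            raise ValueError("need at least two landmarks common to both sets")
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        coord = {n: float(np.dot(pre[n].as_array(), ax)) for n in common}
        landmarks = (min(common, key=coord.get), max(common, key=coord.get))
    first, last = landmarks
    for name in (first, last):
        if name not in pre or name not in post:
            raise ValueError(f"landmark {name!r} missing from one of the sets")
    L_pre = measure_axial_length(AxisSegment(pre[first], pre[last], axis, calibration))
    L_post = measure_axial_length(AxisSegment(post[first], post[last], axis, calibration))
    if L_pre <= 0:
        raise ValueError("pre-excision span is zero along the axis")
    contraction = 100.0 * (L_pre - L_post) / L_pre
    return ContractionResult(L_pre_um=L_pre, L_post_um=L_post, contraction_percent=contraction)


def bead_area(roi: PolygonROI, calibration: PixelCalibration) -> float:
    """Projected area of the extruded notochord bead from a polygon ROI (μm²)."""
    return polygon_area(roi, calibration)


@dataclass
class MembraneTrace:
    """A manually traced membrane point-chain with eligibility annotations.

    ``spans_notochord`` marks traces that touch both sheath lines;
    ``bent`` marks membranes contacting other notochord cells, which are
    deformed and excluded from analysis.
    """

    trace_id: str
    points: np.ndarray  # (N, 2) pixel coordinates, ordered along the membrane
    spans_notochord: bool = True
    bent: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("a trace needs at least 3 (x, y) points")
        self.points = pts


def select_measurement_cell(
    traces: Sequence[MembraneTrace],
    stump_x: float,
    calibration: PixelCalibration,
    offset_um: float = 600.0,
) -> tuple[str, MembraneTriple]:
    """Pick the cell membrane to score and build its curvature triple.

    Among traces that span the notochord width, are not bent by contact
    with other cells, and lie within ``offset_um`` of the stump, the one
    closest to the reference line ``offset_um`` anterior to the stump is
    selected.  Its triple is the two chain endpoints (sheath contacts)
    plus the chain point furthest from their chord (ties broken by the
    smallest y, i.e. most dorsal point).
    """
    px = calibration.pixel_size_um
    ref_x = stump_x - offset_um / px
    best: tuple[float, MembraneTrace] | None = None
    for tr in traces:
        if not tr.spans_notochord or tr.bent:
            continue
        trace_x = 0.5 * (tr.points[0, 0] + tr.points[-1, 0])
        if trace_x < ref_x:
            continue  # more than offset_um from the stump
        d = abs(trace_x - ref_x)
        if best is None or d < best[0]:
            best = (d, tr)
    if best is None:
        raise ValueError(
            "no eligible membrane trace (must span the notochord, be unbent, "
            f"and lie within {offset_um} μm of the stump)"
        )
    tr = best[1]
    a, b = tr.points[0], tr.points[-1]
    chord = b - a
    # perpendicular distance of every chain point to the chord
    rel = tr.points - a
    dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / np.linalg.norm(chord)
    m = dist.max()
    cand = np.nonzero(dist == m)[0]
    apex_idx = cand[np.argmin(tr.points[cand, 1])]
    triple = MembraneTriple(
        sheath_a=Point2D(*a),
        sheath_b=Point2D(*b),
        apex=Point2D(*tr.points[apex_idx]),
        calibration=calibration,
    )
    return tr.trace_id, triple
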