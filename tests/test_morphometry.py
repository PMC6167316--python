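"""Menger curvature, axial lengths, contraction and bead area."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailquant.core import PixelCalibration, Point2D, PolygonROI
from tailquant.morphometry import (
    AxisSegment,
    MembraneTrace,
    MembraneTriple,
    bead_area,
    measure_axial_length,
    measure_contraction,
    menger_curvature,
    select_measurement_cell,
)
from tailquant.synth import CONTRACTION_PRESETS, ContractionParams, gen_contraction_pair, gen_membrane_triples


def circumcircle_radius(pa, pb, pc):
    """Independent oracle: exact circumcentre from perpendicular bisectors.

    Solves the 2x2 linear system |X-A|² = |X-B|² = |X-C|² for the centre
    and returns (centre, radius); None for collinear input.
    """
    A = np.array([[pb[0] - pa[0], pb[1] - pa[1]], [pc[0] - pa[0], pc[1] - pa[1]]])
    b = 0.5 * np.array(
        [
            pb[0] ** 2 - pa[0] ** 2 + pb[1] ** 2 - pa[1] ** 2,
            pc[0] ** 2 - pa[0] ** 2 + pc[1] ** 2 - pa[1] ** 2,
        ]
    )
    if abs(np.linalg.det(A)) < 1e-12:
        return None
    centre = np.linalg.solve(A, b)
    return centre, float(np.hypot(*(np.asarray(pa) - centre)))


def triple(pa, pb, pc, px=1.0):
    return MembraneTriple(
        Point2D(*pa), Point2D(*pb), Point2D(*pc), PixelCalibration(px)
    )


class TestMengerCurvature:
    def test_collinear_points_give_exactly_zero(self):
        res = menger_curvature(triple((0, 0), (0, 50), (0, 100)))
        assert res.kappa == 0.0
        assert res.sign == 0
        assert math.isinf(res.radius_um)

    def test_posterior_bow_on_100um_circle_is_plus_point01(self, cal1):
        triples, entry = gen_membrane_triples([(100.0, "posterior")], seed=0)
        res = menger_curvature(triples[0])
        assert res.kappa == pytest.approx(0.01, rel=1e-9)
        assert res.sign == 1

    def test_anterior_bow_on_50um_circle_is_minus_point02(self):
        triples, _ = gen_membrane_triples([(50.0, "anterior")], seed=0)
        res = menger_curvature(triples[0])
        assert res.kappa == pytest.approx(-0.02, rel=1e-9)
        assert res.sign == -1

    def test_unit_triangle_magnitude(self):
        # 4A/(abc) = 4·1/(2·√2·√2) = 1 for (0,0),(2,0),(1,1)
        res = menger_curvature(triple((0, 0), (2, 0), (1, 1)))
        assert abs(res.kappa) == pytest.approx(1.0, rel=1e-12)

    def test_matches_exact_circumcircle_solver_on_random_triples(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            pts = rng.uniform(-100, 100, size=(3, 2))
            oracle = circumcircle_radius(*pts)
            if oracle is None:
                continue
            res = menger_curvature(triple(*pts))
            if res.kappa == 0.0:
                continue  # solver-degenerate near-collinear case
            assert abs(res.kappa) == pytest.approx(1.0 / oracle[1], rel=1e-9)
            # circumcentre and apex lie on opposite sides of the chord
            centre = oracle[0]
            pa, pb, apex = pts
            chord = pb - pa
            side = lambda p: chord[0] * (p[1] - pa[1]) - chord[1] * (p[0] - pa[0])
            if side(centre) * side(apex) < 0:  # generic case
                assert res.sign != 0
            checked += 1

    def test_pixel_size_scales_curvature_inversely(self):
        pts = ((0, 0), (3, 1), (1, 4))
        k1 = menger_curvature(triple(*pts, px=1.0)).kappa
        k2 = menger_curvature(triple(*pts, px=2.0)).kappa
        assert k2 == pytest.approx(k1 / 2.0, rel=1e-12)

    def test_anterior_posterior_mirror_flips_sign(self):
        pts = np.array([(10.0, 0.0), (11.0, 5.0), (14.0, 2.5)])
        k = menger_curvature(triple(*pts)).kappa
        mirrored = [(-x, y) for x, y in pts]
        km = menger_curvature(triple(*mirrored)).kappa
        assert km == pytest.approx(-k, rel=1e-12)

    @given(
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    @settings(max_examples=50, derandomize=True)
    def test_rigid_motion_preserves_magnitude(self, angle, dx, dy):
        pts = np.array([(0.0, 0.0), (3.0, 1.0), (1.0, 4.0)])
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = pts @ R.T + (dx, dy)
        k0 = abs(menger_curvature(triple(*pts)).kappa)
        k1 = abs(menger_curvature(triple(*moved)).kappa)
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="coincident"):
            triple((0, 0), (0, 0), (1, 1))


class TestAxialLength:
    def test_length_along_axis(self, cal1):
        seg = AxisSegment(Point2D(0, 0), Point2D(100, 0), (1, 0), cal1)
        assert measure_axial_length(seg) == 100.0

    def test_perpendicular_displacement_ignored(self, cal1):
        base = AxisSegment(Point2D(0, 0), Point2D(100, 0), (1, 0), cal1)
        shifted = AxisSegment(Point2D(0, 0), Point2D(100, 37.5), (1, 0), cal1)
        assert measure_axial_length(shifted) == measure_axial_length(base)

    def test_oblique_axis_projection(self, cal1):
        ang = math.radians(30)
        axis = (math.cos(ang), math.sin(ang))
        perp = (-axis[1], axis[0])
        end = Point2D(200 * axis[0] + 15 * perp[0], 200 * axis[1] + 15 * perp[1])
        seg = AxisSegment(Point2D(0, 0), end, axis, cal1)
        assert measure_axial_length(seg) == pytest.approx(200.0, rel=1e-12)

    def test_zero_axis_raises(self, cal1):
        with pytest.raises(ValueError, match="axis"):
            AxisSegment(Point2D(0, 0), Point2D(1, 1), (0, 0), cal1)


class TestContraction:
    def test_arithmetic(self, cal1):
        pre = {"s0": Point2D(0, 0), "s7": Point2D(800, 0)}
        post = {"s0": Point2D(0, 0), "s7": Point2D(764.8, 0)}
        res = measure_contraction(pre, post, (1, 0), cal1)
        assert res.contraction_percent == pytest.approx(4.4, rel=1e-12)

    def test_identical_sets_give_zero(self, cal1):
        pre = {"s0": Point2D(5, 5), "s7": Point2D(805, 5)}
        assert measure_contraction(pre, dict(pre), (1, 0), cal1).contraction_percent == 0.0

    def test_noiseless_generator_recovered_exactly(self, cal1):
        params = ContractionParams(true_contraction_percent=10.0, jitter_sigma_um=0.0)
        pre, post, _ = gen_contraction_pair(params, seed=0)
        res = measure_contraction(pre, post, (1, 0), cal1)
        assert res.contraction_percent == pytest.approx(10.0, abs=1e-9)

    def test_missing_landmark_raises(self, cal1):
        pre = {"s0": Point2D(0, 0), "s7": Point2D(800, 0)}
        post = {"s0": Point2D(0, 0)}
        with pytest.raises(ValueError):
            measure_contraction(pre, post, (1, 0), cal1, landmarks=("s0", "s7"))

    @pytest.mark.parametrize("preset", ["untreated", "pp2", "dpi"])
    def test_mean_recovery_under_jitter_within_03_points(self, preset, cal1):
        truth = CONTRACTION_PRESETS[preset]
        vals = []
        for seed in range(1, 31):
            pre, post, _ = gen_contraction_pair(
                ContractionParams(true_contraction_percent=truth, jitter_sigma_um=2.0),
                seed=seed,
            )
            vals.append(measure_contraction(pre, post, (1, 0), cal1).contraction_percent)
        assert np.mean(vals) == pytest.approx(truth, abs=0.3)

    def test_oblique_axis_recovery(self, cal1):
        params = ContractionParams(
            true_contraction_percent=4.4, jitter_sigma_um=0.0, axis=(2.0, 1.0)
        )
        pre, post, _ = gen_contraction_pair(params, seed=0)
        res = measure_contraction(pre, post, (2.0, 1.0), cal1)
        assert res.contraction_percent == pytest.approx(4.4, abs=1e-9)


class TestBeadArea:
    def test_square_roi(self, cal1):
        roi = PolygonROI([Point2D(0, 0), Point2D(20, 0), Point2D(20, 20), Point2D(0, 20)])
        assert bead_area(roi, cal1) == 400.0

    def test_32gon_approximates_circle_within_1_percent(self, cal1):
        angles = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        roi = PolygonROI([Point2D(50 * np.cos(a), 50 * np.sin(a)) for a in angles])
        assert bead_area(roi, cal1) == pytest.approx(np.pi * 50**2, rel=0.01)


def chain_on_circle(trace_id, x0, radius=60.0, bow=1.0, n=25, **kw):
    """Membrane chain bulging `bow`-ward from a vertical chord at x0."""
    half = 20.0
    c = np.array([x0 - bow * (radius - 1.0), 150.0])
    phi = np.arcsin(half / radius)
    angs = np.linspace(-phi, phi, n)
    pts = np.column_stack([c[0] + bow * radius * np.cos(angs), c[1] + radius * np.sin(angs)])
    return MembraneTrace(trace_id, pts, **kw)


class TestCellSelection:
    def test_trace_nearest_600um_line_is_chosen(self, cal1):
        stump = 1000.0
        traces = [
            chain_on_circle("d580", stump - 580),
            chain_on_circle("d450", stump - 450),
            chain_on_circle("d300", stump - 300),
        ]
        chosen, _ = select_measurement_cell(traces, stump, cal1)
        assert chosen == "d580"

    def test_bent_and_nonspanning_traces_are_ineligible(self, cal1):
        traces = [
            chain_on_circle("bent", 500, bent=True),
            chain_on_circle("partial", 500, spans_notochord=False),
        ]
        with pytest.raises(ValueError, match="eligible"):
            select_measurement_cell(traces, 1000.0, cal1)

    def test_apex_is_chain_point_furthest_from_chord(self, cal1):
        tr = chain_on_circle("t", 600)
        _, triple = select_measurement_cell([tr], 1000.0, cal1)
        a, b = tr.points[0], tr.points[-1]
        chord = b - a
        rel = tr.points - a
        dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / np.linalg.norm(chord)
        best = tr.points[np.argmax(dist)]
        assert (triple.apex.x, triple.apex.y) == (best[0], best[1])

    def test_selected_triple_recovers_generator_radius(self, cal1):
        tr = chain_on_circle("t", 800, radius=75.0, bow=1.0)
        _, triple = select_measurement_cell([tr], 1000.0, cal1)
        res = menger_curvature(triple)
        assert res.kappa == pytest.approx(1 / 75.0, rel=1e-6)
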