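"""The four flight-performance metrics and performance-surface assembly."""

import numpy as np
import pytest
import shapely

from conftest import circle, ellipse, fake_grid, rectangle, square, star_polygon
from wingmorph.errors import ParameterError
from wingmorph.morphospace import TheoreticalGrid
from wingmorph.outline import Outline, canonicalise, resample
from wingmorph.performance import (
    AgilityParams,
    aspect_ratio,
    build_surface,
    pitch_agility,
    second_moment,
    second_moment_nondim,
    tip_angle,
)
from wingmorph.synthetic import PlanformParams, generate_planform


class TestAspectRatio:
    @pytest.mark.parametrize(
        "outline, expected",
        [
            (square(), 1.0),
            (rectangle(2, 1), 2.0),
            (ellipse(2, 1, 4000), 16 / (2 * np.pi)),
        ],
    )
    def test_closed_forms(self, outline, expected):
        assert aspect_ratio(outline) == pytest.approx(expected, rel=1e-3)

    def test_scale_invariant(self):
        o = star_polygon(np.random.default_rng(1), 30)
        big = Outline(o.points * 13.0)
        assert aspect_ratio(big) == pytest.approx(aspect_ratio(o), rel=1e-12)


class TestSecondMoment:
    def test_unit_square_exact(self):
        assert second_moment(square()) == pytest.approx(1 / 3, abs=1e-9)

    def test_rectangle_closed_form(self):
        # r2 = c * R^3 / 3 for a rectangle rooted at x = 0
        assert second_moment(rectangle(2, 1)) == pytest.approx(8 / 3, abs=1e-9)

    def test_orientation_invariance(self):
        ccw = square()
        cw = Outline(ccw.points[::-1].copy())
        assert second_moment(cw) == pytest.approx(second_moment(ccw), abs=1e-12)

    @pytest.mark.parametrize("R,c", [(1, 1), (2, 1), (5, 0.3)])
    def test_nondim_rectangle_invariant(self, R, c):
        assert second_moment_nondim(rectangle(R, c)) == pytest.approx(
            np.sqrt(1 / 3), abs=1e-9
        )

    def test_nondim_right_triangle(self):
        # chord tapers linearly to a point at the tip:
        # r2 = c R^3/12, S R^2 = c R^3/2  ->  sqrt(1/6)
        tri = canonicalise([[0, 0], [4, 0], [0, 1.5]])
        assert second_moment_nondim(tri) == pytest.approx(np.sqrt(1 / 6), abs=1e-9)

    def test_nondim_scale_invariant(self):
        o = generate_planform(PlanformParams(taper=0.4, n_points=400))
        scaled = Outline(o.points * 7.3)
        assert second_moment_nondim(scaled) == pytest.approx(
            second_moment_nondim(o), rel=1e-12
        )

    def test_matches_monte_carlo_integral_on_random_polygons(self):
        # light sanity version; the full 20-polygon 0.5% check runs in the
        # acceptance suite with a larger sample
        rng = np.random.default_rng(7)
        for _ in range(8):
            o = star_polygon(rng, n=int(rng.integers(6, 30)))
            pts = o.points.copy()
            pts[:, 0] -= pts[:, 0].min()
            poly = shapely.geometry.Polygon(pts)
            xmin, ymin, xmax, ymax = poly.bounds
            N = 1_000_000
            xs = rng.uniform(xmin, xmax, N)
            ys = rng.uniform(ymin, ymax, N)
            inside = shapely.contains_xy(poly, xs, ys)
            mc = (xmax - xmin) * (ymax - ymin) * np.mean(xs**2 * inside)
            assert second_moment(o) == pytest.approx(mc, rel=0.01)


class TestPitchAgility:
    def test_rectangle_matches_hand_evaluation(self):
        # independent arithmetic: uniform chord c, leading edge at the global
        # maximum y, so the mean quarter-chord is 0.25c, c_rmax = c, x_CG = 0,
        # S = c R, I_yy = c R^3 / 3.
        R, c = 2.0, 1.0
        o = resample(rectangle(R, c), 1200)
        expected = ((0.25 * c / c) ** 0.8 * c) * (c * R) / (c * R**3 / 3)
        got = pitch_agility(o, AgilityParams(m=1.0, n_strips=100))
        assert got == pytest.approx(expected, rel=1e-3)

    def test_unit_mass_factor_is_neutral(self):
        o = resample(rectangle(3, 1), 600)
        a1 = pitch_agility(o, AgilityParams(m=1.0))
        # (m^0.12)^2 multiplies the whole expression
        a2 = pitch_agility(o, AgilityParams(m=2.0))
        assert a2 == pytest.approx(a1 * (2.0**0.12) ** 2, rel=1e-12)

    def test_strip_count_convergence(self):
        o = generate_planform(PlanformParams(taper=0.4, tip_sharpness=1.5))
        a100 = pitch_agility(o, AgilityParams(n_strips=100))
        a200 = pitch_agility(o, AgilityParams(n_strips=200))
        assert a200 == pytest.approx(a100, rel=0.005)

    def test_chordwise_frame_switch_runs_and_differs(self):
        o = generate_planform(PlanformParams(taper=0.4))
        spanwise = pitch_agility(o, AgilityParams(axis="spanwise"))
        chordwise = pitch_agility(o, AgilityParams(axis="chordwise"))
        assert np.isfinite(spanwise) and np.isfinite(chordwise)
        assert spanwise != chordwise

    def test_not_scale_invariant(self):
        # agility carries length units; grid shapes share one standard scale
        o = resample(rectangle(2, 1), 600)
        big = Outline(o.points * 2.0)
        assert pitch_agility(big) == pytest.approx(pitch_agility(o) / 2, rel=1e-6)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            AgilityParams(n_strips=5)
        with pytest.raises(ParameterError):
            AgilityParams(m=0.0)
        with pytest.raises(ParameterError):
            AgilityParams(axis="diagonal")


def wedge(base: float, height: float, n: int = 1200) -> Outline:
    """Tall isoceles wedge pointing in +x: apex at (height, 0)."""
    tri = canonicalise([[0, -base / 2], [height, 0.0], [0, base / 2]])
    return resample(tri, n)


class TestTipAngle:
    def test_flattened_wedge_limit_approaches_180(self):
        # base much wider than the wedge is deep: the boundary through the
        # tip is nearly a straight edge
        o = wedge(10.0, 0.01)
        assert tip_angle(o) == pytest.approx(180.0, abs=1.0)

    def test_isoceles_wedge_recovers_apex_angle(self):
        base, height = 1.0, 4.0  # equal sides ~4.03 >= 2.5 * base
        o = wedge(base, height)
        apex = 2 * np.degrees(np.arctan((base / 2) / height))
        assert tip_angle(o, offset=500) == pytest.approx(apex, abs=0.5)

    def test_bifurcated_tip_uses_leading_edge_prong(self):
        # 24 explicit landmarks, both prong apices exactly at max x; the
        # effective offset is round(500*24/1200) = 10
        pts = np.array(
            [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0),
             (5, 0.1),                       # trailing (lower) prong apex
             (4, 0.5),                       # cleft
             (5, 0.95),                      # leading (upper) prong apex
             (4.5, 1.0), (4, 1.0), (3.5, 1.0), (3, 1.0), (2.5, 1.0),
             (2, 1.0), (1.5, 1.0), (1, 1.0), (0.5, 1.0), (0, 1.0),
             (0, 0.8), (0, 0.6), (0, 0.5), (0, 0.4), (0, 0.3), (0, 0.15)],
            dtype=float,
        )
        o = Outline(pts)
        tip = pts[7]
        v1, v2 = pts[(7 - 10) % 24] - tip, pts[(7 + 10) % 24] - tip
        expected = np.degrees(
            np.arccos(np.dot(v1, v2) / (np.hypot(*v1) * np.hypot(*v2)))
        )
        assert tip_angle(o) == pytest.approx(expected, abs=1e-9)

    def test_chordwise_translation_invariance(self):
        o = wedge(1.0, 4.0)
        shifted = Outline(o.points + np.array([0.0, 123.4]))
        assert tip_angle(shifted) == pytest.approx(tip_angle(o), abs=1e-9)

    def test_offset_scales_with_landmark_count(self):
        o600 = wedge(1.0, 4.0, n=600)
        o1200 = wedge(1.0, 4.0, n=1200)
        assert tip_angle(o600) == pytest.approx(tip_angle(o1200), abs=0.5)

    def test_too_few_landmarks_raises(self):
        o = wedge(1.0, 4.0, n=600)
        with pytest.raises(ParameterError):
            tip_angle(o, offset=1000)


class TestBuildSurface:
    def _two_node_grid(self):
        valid = np.array([[True, False], [True, False]])
        outlines = np.empty((2, 2), dtype=object)
        outlines[0, 0] = rectangle(2, 2)  # AR = 1
        outlines[1, 0] = rectangle(6, 1)  # AR = 6
        return fake_grid(valid, outlines)

    def test_min_max_normalisation_and_peak(self):
        grid = self._two_node_grid()
        s = build_surface(grid, "AR", "high_optimal")
        assert s.norm[0, 0] == pytest.approx(0.0)
        assert s.norm[1, 0] == pytest.approx(1.0)
        assert s.peak_idx == (1, 0)
        assert np.isnan(s.norm[0, 1])

    def test_direction_inversion_swaps_peak(self):
        grid = self._two_node_grid()
        s = build_surface(grid, "AR", "low_optimal")
        assert s.peak_idx == (0, 0)
        assert s.norm[0, 0] == pytest.approx(1.0)

    def test_constant_metric_flagged_degenerate(self):
        valid = np.array([[True, True]])
        outlines = np.empty((1, 2), dtype=object)
        outlines[0, 0] = rectangle(2, 1)
        outlines[0, 1] = rectangle(2, 1)
        s = build_surface(fake_grid(valid, outlines), "AR")
        assert s.degenerate
        assert np.all(s.norm[valid] == 0.0)

    def test_all_invalid_grid_raises(self):
        with pytest.raises(ParameterError):
            build_surface(fake_grid(np.zeros((2, 2), bool)), "AR")

    def test_surfaces_deterministic(self, small_grid):
        a = build_surface(small_grid, "2MA")
        b = build_surface(small_grid, "2MA")
        assert np.array_equal(a.norm, b.norm, equal_nan=True)
        assert a.peak_idx == b.peak_idx
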