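"""Anatomical endpoint construction: end lines, equal-angle cut, trimming."""

import numpy as np
import pytest

from femurbow.errors import LandmarkConstructionError, ParameterError
from femurbow.geometry import Line2D, Polyline, arc_length, polyline_distance
from femurbow.landmarks import (
    BorderPair,
    construct_landmarks,
    distal_line_and_canal_ends,
    equal_angle_proximal_line,
    proximal_canal_ends,
    trim_to_endpoints,
)

from conftest import rigid_transform


def horizontal_pair(y_up=0.0, y_lo=40.0, x0=0.0, x1=200.0, n=201, structure="outline"):
    x = np.linspace(x0, x1, n)
    return BorderPair(
        upper=Polyline(np.column_stack([x, np.full(n, y_up)])),
        lower=Polyline(np.column_stack([x, np.full(n, y_lo)])),
        structure=structure,
    )


class TestDistalLine:
    def test_vertical_cut_through_horizontal_canal(self):
        canal = horizontal_pair(y_up=10.0, y_lo=30.0, structure="canal")
        line, a, b = distal_line_and_canal_ends((100.0, 0.0), (100.0, 40.0), canal)
        np.testing.assert_allclose(a, [100.0, 10.0], atol=1e-9)
        np.testing.assert_allclose(b, [100.0, 30.0], atol=1e-9)

    def test_identical_points_rejected(self):
        canal = horizontal_pair(structure="canal")
        with pytest.raises(ParameterError):
            distal_line_and_canal_ends((5.0, 5.0), (5.0, 5.0), canal)

    def test_annular_phantom_matches_circle_line_crossing(self):
        from femurbow.synthetic import generate_annular_pair

        pair, lm, truth = generate_annular_pair(
            radius=900.0, width=60.0, extent=30.0, structure="canal"
        )
        # closed form: the radial end line meets circle r at center + r*u(theta)
        center = np.array([940.0, 940.0])  # r_up + 10 by construction
        th_d = np.deg2rad(-75.0)
        u = np.array([np.cos(th_d), np.sin(th_d)])
        line, a, b = distal_line_and_canal_ends(lm.p1, lm.p2, pair)
        np.testing.assert_allclose(a, center + 930.0 * u, atol=0.5)
        np.testing.assert_allclose(b, center + 870.0 * u, atol=0.5)

    def test_missing_crossing_is_an_error(self):
        canal = horizontal_pair(y_up=10.0, y_lo=30.0, x0=0.0, x1=50.0, structure="canal")
        with pytest.raises(LandmarkConstructionError):
            distal_line_and_canal_ends((100.0, 0.0), (100.0, 40.0), canal)


class TestEqualAngleLine:
    def test_parallel_borders_give_perpendicular(self):
        outline = horizontal_pair(y_up=0.0, y_lo=40.0)
        line, p4 = equal_angle_proximal_line((100.0, 40.0), outline)
        # vertical cut, p4 directly above p3
        assert abs(abs(line.angle_deg % 180.0) - 90.0) < 1e-6
        np.testing.assert_allclose(p4, [100.0, 0.0], atol=1e-6)

    def test_symmetric_wedge_yields_symmetry_axis(self):
        # borders mirror-symmetric about the vertical through p3
        x = np.linspace(-100.0, 100.0, 401)
        upper = np.column_stack([x, -0.15 * np.abs(x)])  # V-shape apexed at x=0
        lower = np.column_stack([x, np.full_like(x, 50.0)])
        outline = BorderPair(Polyline(upper), Polyline(lower), "outline")
        line, p4 = equal_angle_proximal_line((0.0, 50.0), outline)
        assert abs(abs(line.angle_deg % 180.0) - 90.0) < 0.1
        assert abs(p4[0]) < 0.2

    def test_matches_exhaustive_sweep_on_smooth_borders(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0.0, 300.0, 600)
        for _ in range(3):
            c_up = rng.uniform(-2e-4, 2e-4)
            c_lo = rng.uniform(-2e-4, 2e-4)
            upper = np.column_stack([x, 0.08 * x + c_up * (x - 150) ** 2])
            lower = np.column_stack([x, 90.0 - 0.05 * x + c_lo * (x - 150) ** 2])
            outline = BorderPair(Polyline(upper), Polyline(lower), "outline")
            p3 = lower[300]
            line, p4 = equal_angle_proximal_line(p3, outline)

            # oracle: exhaustive 0.01-degree sweep of the angle difference
            from femurbow.geometry import intersect_line_polyline, local_tangent_angle
            from femurbow.landmarks import _acute_between, _default_window

            w_lo, w_up = _default_window(outline.lower), _default_window(outline.upper)
            from femurbow.geometry import project_point

            _, s3, _ = project_point(outline.lower, p3)
            tau_lo = local_tangent_angle(outline.lower, s3, w_lo)
            best, best_res = None, np.inf
            for phi in np.arange(tau_lo + 30.0, tau_lo + 150.0, 0.01):
                hits = intersect_line_polyline(Line2D(p3, phi), outline.upper)
                if not hits:
                    continue
                pt, _, s_hit = min(hits, key=lambda h: np.hypot(*(h[0] - p3)))
                tau_up = local_tangent_angle(outline.upper, s_hit, w_up)
                res = abs(_acute_between(phi, tau_lo) - _acute_between(phi, tau_up))
                if res < best_res:
                    best, best_res = phi, res
            diff = abs(line.angle_deg - best) % 180.0
            assert min(diff, 180.0 - diff) < 0.05

    def test_point_off_border_rejected(self):
        outline = horizontal_pair()
        with pytest.raises(LandmarkConstructionError):
            equal_angle_proximal_line((100.0, 45.0), outline)


class TestProximalCanalEnds:
    def test_vertical_line_through_horizontal_canal(self):
        canal = horizontal_pair(y_up=10.0, y_lo=30.0, structure="canal")
        c, d = proximal_canal_ends(Line2D((60.0, 0.0), 90.0), canal)
        assert c[0] == pytest.approx(60.0) and d[0] == pytest.approx(60.0)
        assert c[1] == pytest.approx(10.0) and d[1] == pytest.approx(30.0)

    def test_line_missing_canal_is_an_error(self):
        canal = horizontal_pair(y_up=10.0, y_lo=30.0, x0=0.0, x1=50.0, structure="canal")
        with pytest.raises(LandmarkConstructionError):
            proximal_canal_ends(Line2D((100.0, 0.0), 90.0), canal)


class TestTrim:
    def test_horizontal_border_clipped_between_x_positions(self):
        pair = horizontal_pair(x0=0.0, x1=100.0, n=101)
        out = trim_to_endpoints(pair, (10.0, 0.0), (90.0, 0.0), (10.0, 40.0), (90.0, 40.0))
        for border, y in ((out.upper, 0.0), (out.lower, 40.0)):
            assert border.xy[0, 0] == pytest.approx(10.0)
            assert border.xy[-1, 0] == pytest.approx(90.0)
            np.testing.assert_allclose(border.xy[:, 1], y, atol=1e-9)

    def test_trim_at_existing_vertices_preserves_them(self):
        pair = horizontal_pair(x0=0.0, x1=100.0, n=11)  # vertices every 10 px
        out = trim_to_endpoints(pair, (20.0, 0.0), (80.0, 0.0), (20.0, 40.0), (80.0, 40.0))
        np.testing.assert_allclose(out.upper.xy[:, 0], np.arange(20.0, 81.0, 10.0))

    def test_arc_sub_length_matches_closed_form(self):
        th = np.linspace(0.0, 1.0, 2000)
        arc = 500.0 * np.column_stack([np.cos(th), np.sin(th)])
        pair = BorderPair(Polyline(arc), Polyline(arc + [0.0, 60.0]), "outline")
        a0, a1 = 0.2, 0.8
        pts = [500.0 * np.array([np.cos(a), np.sin(a)]) for a in (a0, a1)]
        out = trim_to_endpoints(pair, pts[0], pts[1], pts[0] + [0, 60], pts[1] + [0, 60])
        assert arc_length(out.upper.xy) == pytest.approx(500.0 * (a1 - a0), rel=1e-3)

    def test_endpoint_off_border_rejected(self):
        pair = horizontal_pair()
        with pytest.raises(LandmarkConstructionError):
            trim_to_endpoints(pair, (10.0, 5.0), (90.0, 0.0), (10.0, 40.0), (90.0, 40.0))


class TestLandmarkSetProperties:
    def test_derived_points_lie_on_their_borders(self, coarse_phantom):
        outline, canal, lm_true, _ = coarse_phantom
        lm = construct_landmarks(lm_true.p1, lm_true.p2, lm_true.p3, outline, canal)
        assert polyline_distance(outline.upper, lm.p4[None])[0] < 0.5
        assert polyline_distance(canal.upper, np.vstack([lm.a, lm.c])).max() < 0.5
        assert polyline_distance(canal.lower, np.vstack([lm.b, lm.d])).max() < 0.5
        # derived proximal points lie on the proximal line, distal on distal
        assert lm.proximal_line.distance(np.vstack([lm.p4, lm.c, lm.d])).max() < 1e-6
        assert lm.distal_line.distance(np.vstack([lm.a, lm.b])).max() < 1e-6

    def test_equal_angle_residual_within_tolerance(self, coarse_phantom):
        from femurbow.geometry import local_tangent_angle, project_point
        from femurbow.landmarks import _acute_between, _default_window

        outline, canal, lm_true, _ = coarse_phantom
        lm = construct_landmarks(lm_true.p1, lm_true.p2, lm_true.p3, outline, canal)
        _, s3, _ = project_point(outline.lower, lm.p3)
        _, s4, _ = project_point(outline.upper, lm.p4)
        tau_lo = local_tangent_angle(outline.lower, s3, _default_window(outline.lower))
        tau_up = local_tangent_angle(outline.upper, s4, _default_window(outline.upper))
        phi = lm.proximal_line.angle_deg
        assert abs(_acute_between(phi, tau_lo) - _acute_between(phi, tau_up)) <= 0.05

    def test_rigid_motion_equivariance(self):
        outline = horizontal_pair(y_up=0.0, y_lo=40.0)
        canal = horizontal_pair(y_up=12.0, y_lo=28.0, structure="canal")
        p1, p2, p3 = (180.0, 0.0), (180.0, 40.0), (20.0, 40.0)
        lm0 = construct_landmarks(p1, p2, p3, outline, canal)

        angle, shift = 25.0, (50.0, -30.0)

        def move_pair(pair):
            return BorderPair(
                Polyline(rigid_transform(pair.upper.xy, angle, shift)),
                Polyline(rigid_transform(pair.lower.xy, angle, shift)),
                pair.structure,
            )

        lm1 = construct_landmarks(
            rigid_transform(p1, angle, shift)[0],
            rigid_transform(p2, angle, shift)[0],
            rigid_transform(p3, angle, shift)[0],
            move_pair(outline),
            move_pair(canal),
        )
        for name in ("p4", "a", "b", "c", "d"):
            moved = rigid_transform(getattr(lm0, name), angle, shift)[0]
            np.testing.assert_allclose(getattr(lm1, name), moved, atol=1e-6)
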