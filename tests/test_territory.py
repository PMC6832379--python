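"""Two-seed territory growth and midline extraction."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from femurbow.errors import ParameterError, TopologyError
from femurbow.geometry import Line2D, Polyline, polyline_distance
from femurbow.landmarks import BorderPair
from femurbow.territory import (
    GridSpec,
    compute_midline,
    extract_midline,
    grow_territories,
    rasterize_borders,
)


def parallel_pair(w=10.0, x1=100.0, structure="outline"):
    up = Polyline(np.array([[0.0, 0.0], [x1, 0.0]]))
    lo = Polyline(np.array([[0.0, w], [x1, w]]))
    return BorderPair(upper=up, lower=lo, structure=structure)


def unit_grid(pair, supersample=1):
    return GridSpec.for_borders(pair, supersample=supersample, margin=3.0)


class TestRasterize:
    def test_parallel_strip_interior_count(self):
        pair = parallel_pair(w=10.0, x1=100.0)
        grid = GridSpec(shape=(15, 105), supersample=1, origin=(-2.0, -2.0))
        s1, s2, dom = rasterize_borders(pair, grid)
        # interior excludes border rows (y=0,10) and end-line columns (x=0,100)
        assert dom.sum() == 9 * 99
        rr, cc = np.nonzero(dom)
        assert rr.min() == 3 and rr.max() == 11  # y = 1..9 at origin -2
        assert cc.min() == 3 and cc.max() == 101

    def test_shared_endpoint_is_topology_error(self):
        up = Polyline(np.array([[0.0, 0.0], [50.0, 10.0]]))
        lo = Polyline(np.array([[0.0, 0.0], [50.0, -10.0]]))
        pair = BorderPair(up, lo, "outline")
        with pytest.raises(TopologyError):
            rasterize_borders(pair, unit_grid(pair))

    def test_annulus_sector_area(self):
        from femurbow.synthetic import generate_annular_pair

        # wide annulus so the one-cell boundary strip is a small fraction
        pair, lm, _ = generate_annular_pair(radius=900.0, width=120.0, extent=40.0, pad_deg=0.0)
        grid = unit_grid(pair, supersample=2)
        _, _, dom = rasterize_borders(pair, grid)
        area_cells = dom.sum() / grid.supersample**2
        theta = np.deg2rad(40.0)
        analytic = 0.5 * theta * (960.0**2 - 840.0**2)
        assert area_cells == pytest.approx(analytic, rel=0.02)


class TestGrow:
    def test_distances_between_parallel_seeds(self):
        shape = (11, 30)
        seed1 = np.zeros(shape, bool)
        seed2 = np.zeros(shape, bool)
        seed1[0, :] = True
        seed2[10, :] = True
        domain = np.zeros(shape, bool)
        domain[1:10, :] = True
        field = grow_territories(seed1, seed2, domain)
        assert field.dist1[3, 15] == 3.0 and field.dist2[3, 15] == 7.0
        assert field.label[3, 15] == 1
        # mirror symmetry of the label field
        lab = field.label[1:10]
        flipped = lab[::-1]
        swapped = np.where(flipped == 1, 2, np.where(flipped == 2, 1, 0))
        np.testing.assert_array_equal(lab, swapped)

    def test_empty_seed_rejected(self):
        z = np.zeros((5, 5), bool)
        s = z.copy()
        s[0, 0] = True
        with pytest.raises(ParameterError):
            grow_territories(s, z, z)

    def test_labels_match_brute_force_nearest_seed(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            shape = (rng.integers(40, 200), rng.integers(40, 200))
            seed1 = np.zeros(shape, bool)
            seed2 = np.zeros(shape, bool)
            seed1[rng.integers(0, shape[0], 15), rng.integers(0, shape[1], 15)] = True
            seed2[rng.integers(0, shape[0], 15), rng.integers(0, shape[1], 15)] = True
            seed2 &= ~seed1
            if not seed2.any():
                continue
            domain = ~(seed1 | seed2)
            field = grow_territories(seed1, seed2, domain)
            rr, cc = np.nonzero(domain)
            cells = np.column_stack([rr, cc]).astype(float)
            d1, _ = cKDTree(np.argwhere(seed1)).query(cells)
            d2, _ = cKDTree(np.argwhere(seed2)).query(cells)
            expect = np.zeros(len(cells), np.int8)
            expect[d1 + 1e-9 < d2] = 1
            expect[d2 + 1e-9 < d1] = 2
            got = field.label[rr, cc]
            ties = np.abs(d1 - d2) <= 1e-9
            np.testing.assert_array_equal(got[~ties], expect[~ties])
            assert np.all(got[ties] == 0)


class TestExtractMidline:
    def _midline_parallel(self, w, supersample):
        pair = parallel_pair(w=w, x1=100.0)
        grid = unit_grid(pair, supersample=supersample)
        s1, s2, dom = rasterize_borders(pair, grid)
        field = grow_territories(s1, s2, dom)
        field.grid = grid
        return extract_midline(
            field,
            Line2D((0.0, 0.0), 90.0),
            Line2D((100.0, 0.0), 90.0),
            source="outline",
            borders=pair,
        )

    @pytest.mark.parametrize("supersample", [1, 2])
    @pytest.mark.parametrize("w", [10.0, 9.0])
    def test_parallel_borders_midline_at_half_width(self, w, supersample):
        mid = self._midline_parallel(w, supersample)
        assert np.max(np.abs(mid.points.xy[:, 1] - w / 2.0)) <= 0.5

    def test_midline_spans_between_end_lines(self):
        mid = self._midline_parallel(10.0, 2)
        xs = mid.points.xy[:, 0]
        assert abs(xs[0] - 0.0) <= 2.0 and abs(xs[-1] - 100.0) <= 2.0

    def test_concentric_arcs_recover_mid_radius(self):
        from femurbow.curvature import fit_circle
        from femurbow.synthetic import generate_annular_pair

        pair, lm, _ = generate_annular_pair(radius=900.0, width=60.0, extent=30.0)
        mid = compute_midline(pair, lm, supersample=2)
        fit = fit_circle(mid.points.xy)
        assert fit.radius == pytest.approx(900.0, rel=0.01)

    def test_equidistance_residual_bounds(self):
        from femurbow.synthetic import generate_annular_pair

        pair, lm, _ = generate_annular_pair(radius=900.0, width=60.0, extent=30.0)
        mid2 = compute_midline(pair, lm, supersample=2)
        assert mid2.equidistance_residual <= 1.0
        mid4 = compute_midline(pair, lm, supersample=4)
        assert mid4.equidistance_residual <= 0.5

    def test_supersample_refinement_convergence(self):
        from femurbow.synthetic import generate_annular_pair

        pair, lm, _ = generate_annular_pair(radius=900.0, width=60.0, extent=30.0)
        mid2 = compute_midline(pair, lm, supersample=2)
        mid4 = compute_midline(pair, lm, supersample=4)
        mean_dev = polyline_distance(mid4.points.xy, mid2.points.xy).mean()
        assert mean_dev <= 0.5


class TestComputeMidline:
    def test_three_arc_phantom_segment_recovery(self, coarse_phantom):
        from femurbow.curvature import measure_radii

        outline, canal, lm, truth = coarse_phantom
        mid = compute_midline(outline, lm)
        m = measure_radii(mid, truth.pixel_spacing)
        for got, want in zip((m.proximal, m.middle, m.distal), truth.radii_mm):
            assert got == pytest.approx(want, rel=0.02)

    def test_canal_midline_agrees_with_outline_midline(self, coarse_phantom):
        # both structures share the same true centerline in the phantom
        outline, canal, lm, truth = coarse_phantom
        mid_o = compute_midline(outline, lm)
        mid_c = compute_midline(canal, lm)
        dev = polyline_distance(mid_o.points.xy, mid_c.points.xy)
        assert dev.mean() < 1.0
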