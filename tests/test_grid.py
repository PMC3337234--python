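import math

import numpy as np
import pytest

from oarvar.contours import ContourSlice, Delineation, Polygon2D
from oarvar.grid import (
    BinaryMask,
    DegenerateMaskError,
    GridExtentError,
    GridSpec,
    delineation_volume,
    polygon_area,
    rasterize,
    signed_distance,
)

from conftest import ball_mask, prism_delineation, square


def brute_force_inside(poly, px, py):
    """Independent pure-Python even-odd point-in-polygon (half-open rule)."""
    verts = poly.vertices
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def random_polygon(rng, max_vertices=12):
    n = int(rng.integers(3, max_vertices + 1))
    pts = rng.uniform(2.0, 28.0, size=(n, 2))
    return Polygon2D(tuple(map(tuple, pts)))


class TestPolygonArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)

    def test_right_triangle(self):
        tri = Polygon2D(((0, 0), (10, 0), (0, 10)))
        assert polygon_area(tri) == pytest.approx(50.0)

    def test_orientation_invariance(self):
        cw = Polygon2D(((0, 0), (0, 10), (10, 10), (10, 0)))
        ccw = Polygon2D(((0, 0), (10, 0), (10, 10), (0, 10)))
        assert polygon_area(cw) == pytest.approx(polygon_area(ccw))


class TestDelineationVolume:
    def test_prism_exact(self, prism):
        assert delineation_volume(prism) == pytest.approx(1.0)

    def test_even_odd_hole(self):
        outer = square(10.0)
        inner = square(5.0, x0=2.5, y0=2.5)
        sl = ContourSlice(z=0.0, polygons=(outer, inner))
        d = Delineation(
            patient_id="p", scan_time="plan", observer_id="o", organ="x",
            laterality="left", slice_spacing=2.0, slices=(sl,),
        )
        # net area 75 mm^2 per slice
        assert delineation_volume(d) == pytest.approx(75.0 * 2.0 / 1000.0)

    def test_sliced_sphere_close_to_analytic(self):
        r, dz = 10.0, 2.0
        slices = []
        for k in range(-4, 5):
            z = k * dz
            chord = math.sqrt(r**2 - z**2)
            ang = 2 * np.pi * np.arange(128) / 128
            poly = Polygon2D(
                tuple((chord * np.cos(a), chord * np.sin(a)) for a in ang)
            )
            slices.append(ContourSlice(z=z, polygons=(poly,)))
        d = Delineation(
            patient_id="p", scan_time="plan", observer_id="o", organ="x",
            laterality="left", slice_spacing=dz, slices=tuple(slices),
        )
        analytic = 4.0 / 3.0 * math.pi * r**3 / 1000.0
        assert delineation_volume(d) == pytest.approx(analytic, rel=0.02)

    def test_empty_volume_zero(self):
        d = Delineation(
            patient_id="p", scan_time="plan", observer_id="o", organ="x",
            laterality="left", slice_spacing=2.0, slices=(),
        )
        assert delineation_volume(d) == 0.0


class TestRasterize:
    def test_square_voxel_count(self):
        # edges midway between voxel centers: exactly 100 voxels per slice
        d = prism_delineation(side=10.0, n_slices=1)
        grid = GridSpec((0.5, 0.5, 0.0), (1.0, 1.0, 2.0), (12, 12, 1))
        m = rasterize(d, grid)
        assert m.voxel_count == 100

    def test_empty_delineation_all_false(self):
        d = Delineation(
            patient_id="p", scan_time="plan", observer_id="o", organ="x",
            laterality="left", slice_spacing=2.0, slices=(),
        )
        grid = GridSpec((0, 0, 0), (1, 1, 1), (5, 5, 5))
        assert rasterize(d, grid).is_empty()

    def test_prism_voxel_volume_matches_polygon_volume(self, prism):
        grid = GridSpec((0.5, 0.5, 0.0), (1.0, 1.0, 2.0), (12, 12, 5))
        m = rasterize(prism, grid)
        assert m.volume_cm3 == pytest.approx(delineation_volume(prism))

    def test_extent_error_lists_axes(self):
        d = prism_delineation(side=50.0)
        grid = GridSpec((0, 0, 0), (1, 1, 2), (10, 10, 5))
        with pytest.raises(GridExtentError, match="x"):
            rasterize(d, grid)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_polygon(rng)
        grid = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (30, 30, 1))
        d = Delineation(
            patient_id="p", scan_time="plan", observer_id="o", organ="x",
            laterality="left", slice_spacing=1.0,
            slices=(ContourSlice(z=0.0, polygons=(poly,)),),
        )
        m = rasterize(d, grid)
        xs, ys = grid.axis_centers(0), grid.axis_centers(1)
        for i, px in enumerate(xs):
            for j, py in enumerate(ys):
                assert m.occupancy[i, j, 0] == brute_force_inside(poly, px, py)

    def test_volume_convergence_on_smooth_phantom(self):
        # voxel-count volume approaches the polygon-slab volume on fine grids
        rng = np.random.default_rng(7)
        for _ in range(3):
            a, b = rng.uniform(6, 12, 2)
            e = rng.uniform(1.5, 3.5)
            slices = []
            for k in range(-4, 5):
                z = 2.0 * k
                f = 1.0 - abs(z / 10.0) ** e
                if f <= 0:
                    continue
                sa, sb = a * f ** (1 / e), b * f ** (1 / e)
                ang = 2 * np.pi * np.arange(96) / 96
                poly = Polygon2D(
                    tuple((sa * np.cos(t), sb * np.sin(t)) for t in ang)
                )
                slices.append(ContourSlice(z=z, polygons=(poly,)))
            d = Delineation(
                patient_id="p", scan_time="plan", observer_id="o", organ="x",
                laterality="left", slice_spacing=2.0, slices=tuple(slices),
            )
            grid = GridSpec((-14.0, -14.0, -8.0), (0.5, 0.5, 2.0), (57, 57, 9))
            m = rasterize(d, grid)
            assert m.volume_cm3 == pytest.approx(delineation_volume(d), rel=0.03)


class TestSignedDistance:
    def test_ball_center_and_outside(self, ball_grid):
        m = ball_mask(10.0, ball_grid)
        sdf = signed_distance(m)
        diag = math.sqrt(3.0)
        center = sdf.values[15, 15, 15]
        assert abs(center - (-10.0)) < diag
        outside = sdf.sample(np.array([[15.0, 0.0, 0.0]]))[0]
        assert abs(outside - 5.0) < diag

    def test_sign_convention(self, ball_grid):
        m = ball_mask(6.0, ball_grid)
        sdf = signed_distance(m)
        assert np.all(sdf.values[m.occupancy] <= 0)
        assert np.all(sdf.values[~m.occupancy] >= 0)

    def test_complement_negation(self, ball_grid):
        m = ball_mask(8.0, ball_grid)
        comp = BinaryMask(ball_grid, ~m.occupancy)
        a = signed_distance(m).values
        b = signed_distance(comp).values
        # equal magnitudes, opposite signs, up to the voxel boundary band;
        # compared away from the grid border where the complement's padded
        # iso-surface adds an artificial outer boundary
        xs = ball_grid.axis_centers(0)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        near = X**2 + Y**2 + Z**2 <= 12.0**2
        assert np.abs(a + b)[near].max() <= math.sqrt(3.0)

    def test_degenerate_masks_raise(self, ball_grid):
        empty = BinaryMask(ball_grid, np.zeros(ball_grid.shape, bool))
        full = BinaryMask(ball_grid, np.ones(ball_grid.shape, bool))
        with pytest.raises(DegenerateMaskError):
            signed_distance(empty)
        with pytest.raises(DegenerateMaskError):
            signed_distance(full)
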