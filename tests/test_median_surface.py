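import numpy as np
import pytest

from oarvar.grid import BinaryMask, DegenerateMaskError, GridSpec, rasterize
from oarvar.median_surface import (
    LocalSDField,
    MedianSurface,
    RegionSpec,
    assign_regions,
    compute_median_surface,
    default_region_specs,
    local_sd,
    majority_mask,
    regional_sd,
    with_regions,
    write_ply,
)

from conftest import ball_mask, prism_delineation


BALL_VOLUME_10 = 4.0 / 3.0 * np.pi * 1000.0


class TestComputeMedianSurface:
    def test_unanimous_observers(self, ball_grid):
        masks = [ball_mask(10.0, ball_grid) for _ in range(5)]
        surf = compute_median_surface(masks)
        voxel_volume = masks[0].volume_cm3 * 1000.0
        assert surf.enclosed_volume_mm3 == pytest.approx(voxel_volume, rel=0.10)

    def test_concentric_balls_median_is_middle(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        assert surf.enclosed_volume_mm3 == pytest.approx(BALL_VOLUME_10, rel=0.05)

    def test_disjoint_two_observers_degenerate(self, ball_grid):
        a = ball_mask(4.0, ball_grid, center=(-8, 0, 0))
        b = ball_mask(4.0, ball_grid, center=(8, 0, 0))
        with pytest.raises(DegenerateMaskError):
            compute_median_surface([a, b])

    def test_two_observer_tie_shell_falls_outside(self, ball_grid):
        # exactly-0.5 occupancy (disagreement shell) must not be interior
        a = ball_mask(8.0, ball_grid)
        b = ball_mask(11.0, ball_grid)
        surf = compute_median_surface([a, b])
        assert surf.enclosed_volume_mm3 == pytest.approx(
            a.volume_cm3 * 1000.0, rel=0.10
        )

    def test_grid_mismatch(self, ball_grid):
        other = GridSpec((0, 0, 0), (1, 1, 1), (31, 31, 31))
        with pytest.raises(ValueError):
            compute_median_surface(
                [ball_mask(8.0, ball_grid), ball_mask(8.0, other)]
            )

    def test_surface_is_closed(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        counts = surf.edge_face_counts()
        assert set(counts.values()) == {2}


class TestLocalSD:
    def test_identical_observers_zero(self, ball_grid):
        masks = [ball_mask(9.0, ball_grid) for _ in range(5)]
        surf = compute_median_surface(masks)
        f = local_sd(surf, masks)
        assert f.global_sd == 0.0
        assert np.all(f.vertex_sd == 0.0)

    def test_concentric_balls_sd(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        f = local_sd(surf, concentric_balls)
        # distances ~ {-2,-1,0,1,2}: sd = sqrt(10/4) = 1.5811
        assert f.global_sd == pytest.approx(1.5811, abs=0.15)
        assert f.n_observers == 5

    def test_shifted_observer_polar_maxima(self, ball_grid):
        masks = [ball_mask(10.0, ball_grid) for _ in range(4)]
        masks.append(ball_mask(10.0, ball_grid, center=(2.0, 0.0, 0.0)))
        surf = compute_median_surface(masks)
        f = local_sd(surf, masks)
        v = surf.vertices
        on_x_poles = np.abs(np.abs(v[:, 0]) - 10.0) < 1.5
        on_x_poles &= (np.abs(v[:, 1]) < 3) & (np.abs(v[:, 2]) < 3)
        on_y_poles = np.abs(np.abs(v[:, 1]) - 10.0) < 1.5
        on_y_poles &= (np.abs(v[:, 0]) < 3) & (np.abs(v[:, 2]) < 3)
        assert f.vertex_sd[on_x_poles].mean() > 2.0 * f.vertex_sd[on_y_poles].mean()

    def test_degenerate_observer_excluded(self, ball_grid):
        masks = [ball_mask(r, ball_grid) for r in (9.0, 10.0, 11.0)]
        masks.append(BinaryMask(ball_grid, np.zeros(ball_grid.shape, bool)))
        surf = compute_median_surface(masks[:3])
        f = local_sd(surf, masks)
        assert f.n_observers == 3

    def test_translation_equivariance(self, ball_grid):
        masks = [ball_mask(r, ball_grid) for r in (8.0, 9.0, 10.0, 11.0, 12.0)]
        surf = compute_median_surface(masks)
        g1 = local_sd(surf, masks).global_sd
        shifted_grid = GridSpec(
            tuple(o + 7.0 for o in ball_grid.origin),
            ball_grid.spacing, ball_grid.shape,
        )
        shifted = [BinaryMask(shifted_grid, m.occupancy) for m in masks]
        g2 = local_sd(compute_median_surface(shifted), shifted).global_sd
        assert g1 == pytest.approx(g2, abs=0.05)

    def test_added_median_observer_never_increases_ss(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        dists5 = []
        from oarvar.grid import signed_distance

        for m in concentric_balls:
            dists5.append(signed_distance(m).sample(surf.vertices))
        dists5 = np.vstack(dists5)
        median_ball = concentric_balls[2]
        d6 = signed_distance(median_ball).sample(surf.vertices)
        stack6 = np.vstack([dists5, d6])
        ss5 = ((dists5 - dists5.mean(axis=0)) ** 2).sum(axis=0)
        ss6 = ((stack6 - stack6.mean(axis=0)) ** 2).sum(axis=0)
        # SS is unchanged when the added value equals the local mean; the
        # median observer's distances deviate from it only by voxelization
        assert np.all(ss6 <= ss5 + 0.1)

    def test_convergence_under_grid_refinement(self):
        def cohort(spacing):
            n = int(round(31.0 / spacing)) | 1
            half = (n - 1) / 2 * spacing
            grid = GridSpec((-half, -half, -15.0), (spacing, spacing, 1.0), (n, n, 31))
            return [ball_mask(r, grid) for r in (8.0, 9.0, 10.0, 11.0, 12.0)]

        coarse = cohort(1.0)
        fine = cohort(0.5)
        g1 = local_sd(compute_median_surface(coarse), coarse).global_sd
        g2 = local_sd(compute_median_surface(fine), fine).global_sd
        assert abs(g1 - g2) / g2 < 0.05


class TestAssignRegions:
    def _prism_surface(self, n_slices=20, side=20.0):
        d = prism_delineation(side=side, n_slices=n_slices, spacing=2.0)
        grid = GridSpec(
            (-4.0, -4.0, -2.0), (1.0, 1.0, 2.0),
            (int(side) + 9, int(side) + 9, n_slices + 2),
        )
        masks = [rasterize(d, grid) for _ in range(2)]
        return compute_median_surface(masks), masks

    def test_cap_rule_five_slices(self):
        surf, masks = self._prism_surface()
        spec = RegionSpec("parotid_left", cranial_slices=5, caudal_slices=5)
        labels = assign_regions(surf, spec, "left")
        v = surf.vertices
        # occupied planes are z = 0..38; top 5 planes start at z = 30
        assert set(labels[v[:, 2] >= 30.5]) == {"cranial"}
        assert set(labels[v[:, 2] <= 7.5]) == {"caudal"}
        body = labels[(v[:, 2] > 8.5) & (v[:, 2] < 29.5)]
        assert set(body) <= {"medial", "lateral", "anterior", "posterior"}

    def test_quadrants_lps_left_organ(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        spec = RegionSpec("ball", cranial_slices=1, caudal_slices=1)
        labels = assign_regions(surf, spec, "left")
        v = surf.vertices
        eq = np.abs(v[:, 2]) < 2.0  # equatorial band, away from caps

        def label_at(x, y):
            sel = eq & (np.hypot(v[:, 0] - x, v[:, 1] - y) < 2.0)
            values, counts = np.unique(labels[sel], return_counts=True)
            return values[np.argmax(counts)]

        assert label_at(-10, 0) == "medial"
        assert label_at(10, 0) == "lateral"
        assert label_at(0, -10) == "anterior"
        assert label_at(0, 10) == "posterior"

    def test_quadrants_right_organ_mirrored(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        spec = RegionSpec("ball", cranial_slices=1, caudal_slices=1)
        labels = assign_regions(surf, spec, "right")
        v = surf.vertices
        eq = np.abs(v[:, 2]) < 2.0
        sel = eq & (np.hypot(v[:, 0] - 10, v[:, 1]) < 2.0)
        values, counts = np.unique(labels[sel], return_counts=True)
        assert values[np.argmax(counts)] == "medial"

    def test_landmark_rule(self, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        spec = RegionSpec("spinal_cord", landmarks=(4.0, -6.0), quadrants=False)
        labels = assign_regions(surf, spec, "midline")
        v = surf.vertices
        assert set(labels[v[:, 2] > 4.5]) == {"cranial"}
        assert set(labels[np.abs(v[:, 2]) < 3.5]) == {"medial"}
        assert set(labels[v[:, 2] < -6.5]) == {"caudal"}

    def test_landmark_thresholds_spec_points(self):
        # synthetic thresholds: z=50 cranial, z=0 medial, z=-80 caudal
        verts = np.array([[0, 0, 50.0], [0, 0, 0.0], [0, 0, -80.0]])
        tris = np.array([[0, 1, 2]])
        grid = GridSpec((-5, -5, -100), (1, 1, 2), (11, 11, 110))
        surf = MedianSurface(verts, tris, grid)
        spec = RegionSpec("spinal_cord", landmarks=(40.0, -60.0), quadrants=False)
        labels = assign_regions(surf, spec, "midline")
        assert list(labels) == ["cranial", "medial", "caudal"]

    def test_closed_slice_rule_ring_vs_horseshoe(self):
        # bottom 3 planes: open horseshoe (caudal); above: closed ring
        grid = GridSpec((-10.0, -10.0, 0.0), (1.0, 1.0, 2.0), (21, 21, 10))
        xs, ys, zs = (grid.axis_centers(a) for a in range(3))
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        rho = np.hypot(X, Y)
        ring = (rho >= 4.0) & (rho <= 8.0)
        open_part = ring & ~((Y < -2) & (np.abs(X) < 3))
        occ = np.where(Z[0, 0] < 6.0, open_part, ring)
        masks = [BinaryMask(grid, occ) for _ in range(2)]
        surf = compute_median_surface(masks)
        spec = RegionSpec("thyroid_cartilage", closed_slice_rule=True)
        labels = assign_regions(surf, spec, "midline", majority=majority_mask(masks))
        v = surf.vertices
        low = labels[v[:, 2] < 5.0]
        assert "caudal" in set(low)
        mid = labels[(v[:, 2] > 7.0) & (v[:, 2] < 15.0)]
        assert "caudal" not in set(mid)

    def test_too_few_planes_midplane_split(self):
        surf, _ = self._prism_surface(n_slices=4)
        spec = RegionSpec("glottic_larynx", cranial_slices=3, caudal_slices=3)
        labels = assign_regions(surf, spec, "midline")
        assert set(labels) <= {"cranial", "caudal"}

    def test_default_specs_cover_studied_organs(self):
        specs = default_region_specs()
        assert len(specs) == 7
        assert specs["parotid_left"].cranial_slices == 5
        assert specs["submandibular_left"].cranial_slices == 3
        assert specs["glottic_larynx"].cranial_slices == 1
        assert specs["spinal_cord"].landmarks is not None
        assert specs["thyroid_cartilage"].closed_slice_rule


class TestRegionalSD:
    def test_constant_field(self):
        f = LocalSDField(np.full(10, 2.0), 2.0, 5)
        labels = np.array(["cranial"] * 4 + ["medial"] * 6)
        out = regional_sd(f, labels)
        assert out == {"cranial": pytest.approx(2.0), "medial": pytest.approx(2.0)}

    def test_piecewise_constant(self):
        sd = np.array([3.0] * 3 + [1.0] * 7)
        f = LocalSDField(sd, float(sd.mean()), 5)
        labels = np.array(["cranial"] * 3 + ["caudal"] * 7)
        out = regional_sd(f, labels)
        assert out["cranial"] == pytest.approx(3.0)
        assert out["caudal"] == pytest.approx(1.0)

    def test_label_length_mismatch(self):
        f = LocalSDField(np.zeros(4), 0.0, 5)
        with pytest.raises(ValueError):
            regional_sd(f, np.array(["cranial"]))


class TestPlyExport:
    def test_write_ply(self, tmp_path, concentric_balls):
        surf = compute_median_surface(concentric_balls)
        f = local_sd(surf, concentric_balls)
        spec = RegionSpec("ball", cranial_slices=2, caudal_slices=2)
        labels = assign_regions(surf, spec, "left")
        path = tmp_path / "mesh.ply"
        write_ply(with_regions(surf, labels), path, f.vertex_sd)
        text = path.read_text().splitlines()
        assert text[0] == "ply"
        n_vertex = int(next(l for l in text if l.startswith("element vertex")).split()[-1])
        assert n_vertex == surf.n_vertices
        body = text[text.index("end_header") + 1:]
        assert len(body) == surf.n_vertices + len(surf.triangles)
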