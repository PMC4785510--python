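"""Surface extraction, splatting projection and boundary-guided registration."""
import numpy as np
import pytest
from scipy import ndimage

from meshdir import (
    ConeBeamGeometry, Volume, default_geometries, dynamic_splat_radius,
    extract_projection_boundary, extract_surface_voxels,
    filter_projected_boundary, register_boundary, splat_project, splat_sigma,
)
from meshdir.boundary import SplatKernelSpec, BoundaryPointSet2D, _BoundaryModel
from meshdir.features import BinaryMask, body_mask
from meshdir.phantom import Ellipsoid, default_phantom, make_phantom
from meshdir.project import ProjectionImage


class TestSurfaceVoxels:
    def test_cube_has_26_surface_voxels(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        surf = extract_surface_voxels(BinaryMask(m))
        assert len(surf) == 26

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        surf = extract_surface_voxels(BinaryMask(m))
        assert len(surf) == 1
        assert np.array_equal(surf.coords[0], [2, 2, 2])

    def test_full_raster_surface_is_outer_shell(self):
        n = 6
        surf = extract_surface_voxels(BinaryMask(np.ones((n, n, n), dtype=bool)))
        assert len(surf) == n ** 3 - (n - 2) ** 3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_surface_voxels(BinaryMask(np.zeros((4, 4, 4), dtype=bool)))


class TestProjectionBoundary:
    def test_disc_boundary_near_analytic_circle(self):
        yy, xx = np.mgrid[:64, :64]
        disc = ((yy - 32) ** 2 + (xx - 32) ** 2) <= 20 ** 2
        pts = extract_projection_boundary(disc.astype(float)).points
        radii = np.hypot(pts[:, 0] - 32, pts[:, 1] - 32)
        assert np.all(np.abs(radii - 20) <= 1.0)

    def test_full_frame_boundary_is_border(self):
        pts = extract_projection_boundary(np.ones((10, 12))).points
        on_border = (
            (pts[:, 0] == 0) | (pts[:, 0] == 9)
            | (pts[:, 1] == 0) | (pts[:, 1] == 11)
        )
        assert np.all(on_border)
        assert len(pts) == 2 * 10 + 2 * 12 - 4

    def test_two_discs_give_two_boundary_loops(self):
        yy, xx = np.mgrid[:64, :64]
        two = (((yy - 20) ** 2 + (xx - 20) ** 2) <= 8 ** 2) | \
              (((yy - 45) ** 2 + (xx - 45) ** 2) <= 8 ** 2)
        pts = extract_projection_boundary(two.astype(float)).points
        img = np.zeros((64, 64), dtype=bool)
        img[pts[:, 0].astype(int), pts[:, 1].astype(int)] = True
        _, n_loops = ndimage.label(img, structure=np.ones((3, 3)))
        assert n_loops == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_projection_boundary(np.zeros((8, 8)))


class TestSplat:
    def test_dynamic_radius_equals_voxel_scale_when_d1_is_d2(self):
        assert dynamic_splat_radius(1.0, 750.0, 750.0) == pytest.approx(1.0)
        assert dynamic_splat_radius(2.0, 500.0, 1000.0) == pytest.approx(4.0)

    def test_sigma_is_057_of_unit_radius(self):
        assert splat_sigma(1.0) == pytest.approx(0.57)
        spec = SplatKernelSpec(r=2.0)
        assert spec.sigma == pytest.approx(1.14)
        assert spec.support_radius == pytest.approx(3 * 1.14)

    def test_kernel_mass_conserved(self):
        vol = default_phantom(24)
        mask = body_mask(vol, 0.01)
        surf = extract_surface_voxels(mask)
        g = ConeBeamGeometry(angle_deg=10.0, det_shape=(96, 96),
                             pixel_pitch_mm=1.0,
                             isocenter_mm=vol.center_world)
        img = splat_project(surf, g, vol, with_kernel=True)
        assert img.pixels.sum() == pytest.approx(len(surf), rel=0.01)

    def test_no_kernel_deposits_count(self):
        vol = default_phantom(24)
        surf = extract_surface_voxels(body_mask(vol, 0.01))
        g = ConeBeamGeometry(angle_deg=10.0, det_shape=(96, 96),
                             pixel_pitch_mm=1.0,
                             isocenter_mm=vol.center_world)
        img = splat_project(surf, g, vol, with_kernel=False)
        assert img.pixels.sum() == pytest.approx(len(surf))


class TestFilterBoundary:
    @pytest.fixture(scope="class")
    def sphere_scene(self):
        n = 32
        c = (n - 1) / 2
        vol = make_phantom((n, n, n),
                           [Ellipsoid((c, c, c), (12, 12, 12), 1.0)])
        mask = body_mask(vol, 0.5)
        surf = extract_surface_voxels(mask)
        geom = ConeBeamGeometry(angle_deg=0.0, det_shape=(96, 96),
                                pixel_pitch_mm=1.0,
                                isocenter_mm=vol.center_world)
        return vol, surf, geom

    def test_retained_points_on_silhouette_circle(self, sphere_scene):
        vol, surf, geom = sphere_scene
        nk = splat_project(surf, geom, vol, with_kernel=False)
        wk = splat_project(surf, geom, vol, with_kernel=True)
        kept = filter_projected_boundary(nk, wk)
        # analytic silhouette radius: sphere radius magnified by SDD/SAD
        r_expect = 12.0 * geom.sdd_mm / geom.sad_mm
        center = (np.array(geom.det_shape) - 1) / 2
        radii = np.linalg.norm(kept.points - center, axis=1)
        assert np.all(np.abs(radii - r_expect) <= 2.5)

    def test_interior_projections_removed(self, sphere_scene):
        vol, surf, geom = sphere_scene
        nk = splat_project(surf, geom, vol, with_kernel=False)
        wk = splat_project(surf, geom, vol, with_kernel=True)
        kept = filter_projected_boundary(nk, wk)
        assert len(kept) < int((nk.pixels > 0).sum())

    def test_empty_silhouette_rejected(self):
        zero = ProjectionImage(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            filter_projected_boundary(zero, zero)


class TestBoundaryEnergy:
    def test_rigid_two_pixel_shift_costs_four_per_point(self):
        line = np.column_stack([np.arange(10, 40, dtype=float),
                                np.full(30, 25.0)])
        target = BoundaryPointSet2D(line)
        shifted = line + np.array([0.0, 2.0])
        d, _ = target.tree.query(shifted)
        assert np.sum(d * d) == pytest.approx(4.0 * len(line))

    def test_coincident_boundaries_have_zero_distance_term(self):
        vol = default_phantom(24)
        mask = body_mask(vol, 0.01)
        from meshdir.features import (density_from_edges,
                                      extract_feature_edges)
        from meshdir.meshing import feature_mesh

        mesh = feature_mesh(60, density_from_edges(
            extract_feature_edges(vol)), mask, vol.shape, seed=2, max_iter=20)
        geoms = default_geometries(2, vol, det_shape=(72, 72),
                                   pixel_pitch_mm=1.2)
        surf = extract_surface_voxels(mask)
        targets = []
        for g in geoms:
            nk = splat_project(surf, g, vol, with_kernel=False)
            wk = splat_project(surf, g, vol, with_kernel=True)
            targets.append(filter_projected_boundary(nk, wk))
        model = _BoundaryModel(surf, targets, geoms, mesh, vol)
        D0 = np.zeros((mesh.n_vertices, 3))
        sel = model.select(D0)
        # build targets from the continuous projected positions of the
        # retained voxels themselves: the distance term must vanish exactly
        world = vol.index_to_world(surf.coords)
        exact_targets = []
        for g, s in zip(geoms, sel):
            row, col, _, _ = g.project_points(world[s])
            exact_targets.append(BoundaryPointSet2D(
                np.column_stack([row, col])))
        model2 = _BoundaryModel(surf, exact_targets, geoms, mesh, vol)
        assert model2.distance_energy(D0, sel) == pytest.approx(0.0, abs=1e-12)


class TestRegisterBoundary:
    @pytest.fixture(scope="class")
    def translated_scene(self):
        from meshdir.features import (density_from_edges,
                                      extract_feature_edges)
        from meshdir.meshing import feature_mesh
        from meshdir.phantom import AnalyticDVF, warp_groundtruth
        from skimage.filters import threshold_otsu

        vol = default_phantom(32)
        mask = body_mask(vol, 0.01)
        mesh = feature_mesh(80, density_from_edges(
            extract_feature_edges(vol)), mask, vol.shape, seed=3, max_iter=30)
        true = AnalyticDVF("translation", amplitude=(2.0, 1.0, 0.0))
        target = warp_groundtruth(vol, true)
        tmask = body_mask(target, 0.01)
        geoms = default_geometries(4, vol, det_shape=(64, 64),
                                   pixel_pitch_mm=1.6)
        targets = []
        for g in geoms:
            st = extract_surface_voxels(tmask)
            wk = splat_project(st, g, target, with_kernel=True)
            sil = ndimage.binary_fill_holes(
                wk.pixels > threshold_otsu(wk.pixels))
            targets.append(extract_projection_boundary(
                ProjectionImage(sil.astype(float))))
        return vol, mask, mesh, geoms, targets

    def test_identical_masks_stay_near_zero(self, translated_scene):
        vol, mask, mesh, geoms, _ = translated_scene
        surf = extract_surface_voxels(mask)
        own_targets = []
        for g in geoms:
            nk = splat_project(surf, g, vol, with_kernel=False)
            wk = splat_project(surf, g, vol, with_kernel=True)
            own_targets.append(filter_projected_boundary(nk, wk))
        D = register_boundary(mask, own_targets, geoms, mesh, vol, mu=10.0,
                              max_iter=5)
        assert np.max(np.abs(D)) < 0.5

    def test_translation_reduces_silhouette_distance(self, translated_scene):
        vol, mask, mesh, geoms, targets = translated_scene
        surf = extract_surface_voxels(mask)
        model = _BoundaryModel(surf, targets, geoms, mesh, vol)
        D = register_boundary(mask, targets, geoms, mesh, vol, mu=10.0,
                              max_iter=10)
        zero = np.zeros_like(D)
        e_before = model.distance_energy(zero, model.select(zero))
        e_after = model.distance_energy(D, model.select(D))
        assert e_after < e_before
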