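"""Particle energies/forces, the kernel width, and tetrahedral mesh assembly."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from meshdir import (
    MetricTensorField, ParticleSet, build_tet_mesh, kernel_width,
)
from meshdir.features import BinaryMask
from meshdir.meshing import (
    bounding_box_corners, embedding_measure, initialize_particles,
    optimize_particles, pair_energy, pair_force, total_energy_grad,
    uniform_orthogonal_mesh, uniform_tet_mesh,
)


class TestKernelWidth:
    def test_unit_volume_per_particle(self):
        assert kernel_width(1000.0, 1000) == pytest.approx(0.3)

    def test_cube_root_homogeneity(self):
        assert kernel_width(2000.0, 10) == pytest.approx(
            2 ** (1 / 3) * kernel_width(1000.0, 10))

    def test_monotone_decreasing_in_particle_count(self):
        sigmas = [kernel_width(1000.0, n) for n in (10, 100, 1000, 10000)]
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))

    def test_zero_particles_rejected(self):
        with pytest.raises(ValueError):
            kernel_width(1000.0, 0)


class TestPairEnergyForce:
    metric = MetricTensorField()  # uniform rho = 1

    def test_coincident_particles_have_unit_energy(self):
        v = np.array([3.0, 4.0, 5.0])
        assert pair_energy(v, v, self.metric, sigma=1.7) == 1.0

    def test_two_sigma_separation_gives_e_minus_one(self):
        sigma = 1.3
        v_i = np.zeros(3)
        v_j = np.array([2 * sigma, 0, 0])
        assert pair_energy(v_i, v_j, self.metric, sigma) == pytest.approx(
            np.exp(-1.0))

    def test_energy_symmetric_in_arguments(self, rng):
        a, b = rng.uniform(0, 10, (2, 3))
        assert pair_energy(a, b, self.metric, 2.0) == pair_energy(
            b, a, self.metric, 2.0)

    def test_higher_density_shrinks_interaction(self):
        dense = MetricTensorField(np.full((8, 8, 8), 2.0))  # rho^(1/3) = 2
        a, b = np.array([2.0, 2, 2]), np.array([5.0, 2, 2])
        assert pair_energy(a, b, dense, 1.5) < pair_energy(a, b, self.metric, 1.5)

    def test_force_zero_at_coincidence(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(pair_force(v, v, self.metric, 1.0), 0.0)

    def test_force_matches_numerical_gradient_of_energy(self, rng):
        sigma = 1.9
        v_i = rng.uniform(0, 5, 3)
        v_j = v_i + rng.uniform(-2, 2, 3)
        f = pair_force(v_i, v_j, self.metric, sigma)
        h = 1e-6
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            fd = (pair_energy(v_i, v_j + e, self.metric, sigma)
                  - pair_energy(v_i, v_j - e, self.metric, sigma)) / (2 * h)
            assert f[ax] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_force_antisymmetric_under_swap(self, rng):
        a, b = rng.uniform(0, 8, (2, 3))
        f_ab = pair_force(a, b, self.metric, 1.4)
        f_ba = pair_force(b, a, self.metric, 1.4)
        assert np.allclose(f_ab, -f_ba, atol=1e-15)

    def test_force_decays_at_large_separation(self):
        a = np.zeros(3)
        far = np.array([100.0, 0, 0])
        assert np.linalg.norm(pair_force(a, far, self.metric, 1.0)) < 1e-30


class TestTotalEnergy:
    metric = MetricTensorField()

    def test_single_particle_has_zero_energy_and_gradient(self):
        e, g = total_energy_grad(ParticleSet(np.zeros((1, 3)), 1.0), self.metric)
        assert e == 0.0 and np.all(g == 0.0)

    def test_truncation_exact_inside_five_sigma(self, rng):
        # all pairs within 5 sigma: truncated sum equals the all-pairs sum
        sigma = 2.0
        pos = rng.uniform(0, 2.5 * sigma, (50, 3))
        e, _ = total_energy_grad(ParticleSet(pos, sigma), self.metric)
        brute = 0.0
        for i in range(50):
            for j in range(50):
                if i != j:
                    d = pos[i] - pos[j]
                    brute += np.exp(-d @ d / (4 * sigma ** 2))
        assert e == pytest.approx(brute, rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        sigma = 1.5
        pos = rng.uniform(0, 12, (30, 3))
        ps = ParticleSet(pos, sigma)
        e, g = total_energy_grad(ps, self.metric)
        h = 1e-6
        for idx in [(0, 0), (7, 1), (19, 2), (29, 0)]:
            p = pos.copy()
            p[idx] += h
            ep, _ = total_energy_grad(ParticleSet(p, sigma), self.metric)
            p[idx] -= 2 * h
            em, _ = total_energy_grad(ParticleSet(p, sigma), self.metric)
            fd = (ep - em) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestOptimizeParticles:
    def test_energy_does_not_increase(self, density32, mask32):
        metric = MetricTensorField.from_density(density32)
        init = initialize_particles(60, metric, mask32, seed=4)
        e0, _ = total_energy_grad(init, metric)
        opt = optimize_particles(init, metric, mask32, max_iter=30)
        e1, _ = total_energy_grad(opt, metric)
        assert e1 <= e0
        # all particles stay inside the body mask
        idx = np.clip(np.round(opt.positions).astype(int), 0, 31)
        assert np.all(mask32.data[idx[:, 0], idx[:, 1], idx[:, 2]])

    def test_adaptive_spacing_denser_near_features(self):
        # single-shell phantom: the body interior reaches phi well above the
        # ramp start, so near-edge and off-edge populations both exist
        from meshdir.features import body_mask, density_from_edges, \
            extract_feature_edges
        from meshdir.phantom import Ellipsoid, make_phantom

        vol = make_phantom((48, 48, 48),
                           [Ellipsoid((23.5, 23.5, 23.5), (20, 18, 19), 1.0)])
        mask = body_mask(vol, 0.5)
        density = density_from_edges(extract_feature_edges(vol))
        metric = MetricTensorField.from_density(density)
        init = initialize_particles(150, metric, mask, seed=7)
        opt = optimize_particles(init, metric, mask, max_iter=40)
        tree = cKDTree(opt.positions)
        nn, _ = tree.query(opt.positions, k=2)
        spacing = nn[:, 1]
        phi = density.phi[tuple(np.round(opt.positions).astype(int).T)]
        near, far = spacing[phi <= 2], spacing[phi > 4]
        assert len(near) > 5 and len(far) > 5
        assert near.mean() < far.mean()

    def test_uniform_density_yields_even_spacing(self):
        # coefficient of variation of nearest-neighbor distances in a cube
        mask = BinaryMask(np.ones((24, 24, 24), dtype=bool))
        metric = MetricTensorField()
        init = initialize_particles(200, metric, mask, seed=11)
        opt = optimize_particles(init, metric, mask, max_iter=80)
        nn, _ = cKDTree(opt.positions).query(opt.positions, k=2)
        d = nn[:, 1]
        assert d.std() / d.mean() < 0.25


class TestTetMesh:
    def test_vertex_count_appends_eight_corners(self, mesh32):
        assert mesh32.n_vertices == 100 + 8
        assert int(mesh32.is_corner.sum()) == 8

    def test_four_interior_particles_all_meshed(self):
        pos = np.array([[5.0, 5, 5], [10, 6, 5], [6, 11, 6], [7, 7, 11]])
        mesh = build_tet_mesh(ParticleSet(pos, 1.0), (16, 16, 16))
        used = np.unique(mesh.tets)
        assert np.all(np.isin(np.arange(4), used))

    def test_degenerate_coplanar_points_rejected(self):
        pos = np.column_stack([np.arange(4), np.arange(4), np.zeros(4)])
        ps = ParticleSet(pos.astype(float) + 1.0, 1.0)
        with pytest.raises(ValueError):
            # corners make the set non-coplanar, so collapse the box too
            build_tet_mesh(ps, (1, 1, 1))

    def test_positive_orientation(self, mesh32):
        v = mesh32.vertices
        t = mesh32.tets
        a, b, c, d = (v[t[:, k]] for k in range(4))
        det = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
        assert np.all(det > 0)

    def test_empty_circumsphere_property_on_small_instance(self, rng):
        pts = rng.uniform(0, 10, (15, 3))
        mesh = build_tet_mesh(ParticleSet(pts, 1.0), (11, 11, 11))
        verts = mesh.vertices
        for tet in mesh.tets[:40]:
            p = verts[tet]
            # circumcenter from |x - c|^2 equal over the 4 vertices
            A = 2 * (p[1:] - p[0])
            rhs = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
            try:
                center = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            radius = np.linalg.norm(p[0] - center)
            others = np.delete(np.arange(len(verts)), tet)
            dist = np.linalg.norm(verts[others] - center, axis=1)
            assert np.all(dist >= radius - 1e-6)


class TestUniformBaselines:
    def test_orthogonal_grid_vertex_count(self):
        mesh = uniform_orthogonal_mesh(64, (33, 33, 33))
        assert mesh.n_vertices == 64  # 4x4x4 lattice includes the corners
        assert int(mesh.is_corner.sum()) == 8

    def test_orthogonal_grid_covers_box(self):
        from meshdir.deform import grid_assignment
        mesh = uniform_orthogonal_mesh(64, (17, 17, 17))
        assign = grid_assignment(mesh, (17, 17, 17))
        assert np.all(assign.tet_ids >= 0)

    def test_uniform_tet_mesh_more_even_than_feature_mesh(self, phantom32,
                                                          density32, mask32,
                                                          mesh32):
        uni = uniform_tet_mesh(100, phantom32.shape, mask32, seed=1,
                               max_iter=40)

        def interior_cv(mesh):
            pos = mesh.vertices[~mesh.is_corner]
            nn, _ = cKDTree(pos).query(pos, k=2)
            d = nn[:, 1]
            return d.std() / d.mean()

        assert interior_cv(uni) < interior_cv(mesh32)

    def test_embedding_measure_weights_by_density(self, density32, mask32):
        plain = embedding_measure(None, mask32)
        weighted = embedding_measure(density32, mask32)
        assert weighted > plain  # rho >= 1 with features present

    def test_corners_span_volume_bounding_box(self):
        corners = bounding_box_corners((10, 20, 30))
        assert corners.shape == (8, 3)
        assert np.all(corners.max(axis=0) == [9, 19, 29])
        assert np.all(corners.min(axis=0) == 0)
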