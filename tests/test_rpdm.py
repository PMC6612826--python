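"""Initial spherical map, area residual/Jacobian, ADMM step, optimizer."""

import numpy as np
import pytest

import cellshape as cs
from cellshape._sphere import quad_signed_areas
from cellshape.rpdm import face_area_targets


class TestInitialParameterization:
    def test_pole_boundary_conditions(self, voxel_sphere):
        mesh = cs.voxels_to_quad_mesh(voxel_sphere)
        poles = cs.graph_diameter_poles(mesh)
        mapping = cs.initial_parameterization(mesh, poles)
        assert mapping.theta[poles[0]] == 0.0
        assert mapping.theta[poles[1]] == np.pi

    def test_interior_theta_strictly_inside(self, voxel_sphere):
        mesh = cs.voxels_to_quad_mesh(voxel_sphere)
        poles = cs.graph_diameter_poles(mesh)
        mapping = cs.initial_parameterization(mesh, poles)
        interior = np.setdiff1d(np.arange(mesh.n_vertices), list(poles))
        assert np.all(mapping.theta[interior] > 0)
        assert np.all(mapping.theta[interior] < np.pi)

    def test_positive_areas_on_voxel_sphere(self, voxel_sphere):
        mesh = cs.voxels_to_quad_mesh(voxel_sphere)
        mapping = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        areas = quad_signed_areas(mapping.theta, mapping.phi, mesh.faces)
        assert (areas > 0).mean() >= 0.99

    def test_identical_poles_rejected(self, voxel_sphere):
        mesh = cs.voxels_to_quad_mesh(voxel_sphere)
        with pytest.raises(ValueError, match="distinct"):
            cs.initial_parameterization(mesh, (3, 3))

    def test_adjacent_poles_rejected(self):
        mesh = cs.voxels_to_quad_mesh(
            cs.VoxelVolume(np.ones((1, 1, 1), bool)))
        e = mesh.edges[0]
        with pytest.raises(ValueError, match="adjacent"):
            cs.initial_parameterization(mesh, (int(e[0]), int(e[1])))


class TestAreaResidualsAndJacobian:
    def test_residuals_sum_to_zero(self, sphere_pipeline):
        mesh, mapping, _ = sphere_pipeline
        residual, _ = cs.compute_area_residuals_and_jacobian(mapping, mesh)
        # signed spherical areas partition the sphere: residuals cancel
        assert abs(residual.sum()) < 1e-8

    def test_jacobian_matches_finite_differences(self):
        # 24-face cube-sphere fixture
        mesh = cs.voxels_to_quad_mesh(
            cs.VoxelVolume(np.ones((2, 2, 1), bool)))
        mapping = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        residual, J = cs.compute_area_residuals_and_jacobian(mapping, mesh)
        V = mesh.n_vertices
        h = 1e-6
        rng = np.random.default_rng(0)
        worst = 0.0
        for c in rng.choice(2 * V, size=30, replace=False):
            th, ph = mapping.theta.copy(), mapping.phi.copy()
            if c < V:
                th[c] += h
            else:
                ph[c - V] += h
            r2 = (quad_signed_areas(th, ph, mesh.faces)
                  - face_area_targets(mesh))
            fd = (r2 - residual) / h
            an = np.asarray(J[:, c].todense()).ravel()
            mask = np.abs(fd) > 1e-7
            if mask.any():
                worst = max(worst, np.max(
                    np.abs(an[mask] - fd[mask]) / np.abs(fd[mask])))
        assert worst < 1e-4

    def test_equal_area_map_near_zero_residual(self):
        # single cube with the exact octant map is symmetric enough that a
        # few optimizer steps drive residuals to ~0
        mesh = cs.voxels_to_quad_mesh(
            cs.VoxelVolume(np.ones((1, 1, 1), bool)))
        mapping = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        opt, diag = cs.optimize_parameterization(
            mesh, mapping, cs.RPDMOptions(max_iter=50, tol=1e-6))
        residual, _ = cs.compute_area_residuals_and_jacobian(opt, mesh)
        assert np.abs(residual).max() < 1e-4


class TestADMMConstrainedLeastSquares:
    def test_slack_bound_matches_unconstrained(self):
        rng = np.random.default_rng(3)
        J = rng.normal(size=(10, 8))
        r = rng.normal(size=10) * 1e-3
        d = cs.admm_constrained_least_squares(J, r, step_bound=100.0,
                                              max_iter=500)
        d_ls = np.linalg.lstsq(J, -r, rcond=None)[0]
        assert np.allclose(d, d_ls, atol=1e-6)

    def test_active_bound_feasible_and_better_than_clipping(self):
        rng = np.random.default_rng(4)
        J = rng.normal(size=(10, 8))
        r = rng.normal(size=10) * 10
        bound = 0.05
        d = cs.admm_constrained_least_squares(J, r, step_bound=bound,
                                              max_iter=500)
        assert np.all(np.abs(d) <= bound + 1e-9)
        d_clip = np.clip(np.linalg.lstsq(J, -r, rcond=None)[0],
                         -bound, bound)
        obj = np.linalg.norm(J @ d + r)
        obj_clip = np.linalg.norm(J @ d_clip + r)
        assert obj <= obj_clip + 1e-9

    def test_zero_residual_gives_zero_step(self):
        J = np.eye(4)
        d = cs.admm_constrained_least_squares(J, np.zeros(4), 1.0)
        assert np.allclose(d, 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            cs.admm_constrained_least_squares(
                np.eye(2), np.array([np.nan, 0.0]), 1.0)


class TestOptimizeParameterization:
    def test_converged_map_stays_put(self):
        mesh = cs.voxels_to_quad_mesh(
            cs.VoxelVolume(np.ones((1, 1, 1), bool)))
        init = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        opt1, _ = cs.optimize_parameterization(
            mesh, init, cs.RPDMOptions(max_iter=50, tol=1e-8))
        opt2, diag2 = cs.optimize_parameterization(
            mesh, opt1, cs.RPDMOptions(max_iter=50, tol=1e-6))
        assert diag2.iterations <= 1
        assert np.abs(opt2.theta - opt1.theta).max() < 1e-8
        assert np.abs(opt2.phi - opt1.phi).max() < 1e-8

    def test_rod_area_ratio_improves(self, voxel_rod):
        mesh = cs.voxels_to_quad_mesh(voxel_rod)
        init = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        targets = face_area_targets(mesh)
        before = np.max(np.abs(quad_signed_areas(
            init.theta, init.phi, mesh.faces)) / targets)
        _, diag = cs.optimize_parameterization(mesh, init)
        assert diag.max_area_ratio < before

    def test_areas_sum_to_4pi_at_every_accepted_iterate(self, voxel_rod):
        mesh = cs.voxels_to_quad_mesh(voxel_rod)
        init = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        mapping = init
        for _ in range(4):
            mapping, _ = cs.optimize_parameterization(
                mesh, mapping, cs.RPDMOptions(max_iter=1))
            total = quad_signed_areas(
                mapping.theta, mapping.phi, mesh.faces).sum()
            assert total == pytest.approx(4 * np.pi, abs=1e-8)

    def test_no_inverted_faces_after_optimization(self, sphere_pipeline):
        mesh, mapping, _ = sphere_pipeline
        areas = quad_signed_areas(mapping.theta, mapping.phi, mesh.faces)
        assert np.all(areas > 0)


class TestParameterizeRobust:
    def test_smooth_ellipsoid_converges_below_2_voxels(self):
        vol = cs.generate_blob_3d(size=22, elongation=1.5, roughness=0.0,
                                  seed=0)
        mesh, mapping, diag = cs.parameterize_robust(
            vol, cs.RPDMOptions(working_order=15))
        assert not diag.failed
        assert diag.reconstruction_error < 2.0

    def test_topology_fix_recorded_in_diagnostics(self):
        vol = np.zeros((16, 16, 10), bool)
        vol[2:14, 2:14, 2:8] = True
        vol[7, 7, :] = False  # tunnel
        mesh, mapping, diag = cs.parameterize_robust(
            cs.VoxelVolume(vol), cs.RPDMOptions(working_order=8))
        assert diag.applied_kernel >= 1
        assert not diag.failed

    def test_reconstruction_error_weakly_decreases_with_iterations(self):
        vol = cs.generate_blob_3d(size=16, roughness=0.2, seed=11)
        fixed, _ = cs.fix_topology(vol)
        mesh = cs.voxels_to_quad_mesh(fixed)
        init = cs.initial_parameterization(
            mesh, cs.graph_diameter_poles(mesh))
        errors = []
        for iters in (0, 4, 12):
            opts = cs.RPDMOptions(max_iter=iters)
            mapping = init if iters == 0 else \
                cs.optimize_parameterization(mesh, init, opts)[0]
            desc = cs.fit_descriptor(mesh, mapping, 10)
            rec = cs.reconstruct_surface(desc, 2562)
            errors.append(cs.hausdorff_distance(mesh.vertices, rec.vertices))
        assert errors[2] <= errors[0] + 0.25  # weak decrease, px tolerance
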