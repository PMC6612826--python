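"""Descriptor PCA shape spaces, latent interpolation, evolution energy."""

import numpy as np
import pytest

import cellshape as cs
from cellshape.shape_space import (descriptor_to_vector,
                                   vector_to_descriptor)


def random_descriptors(n, L=4, seed=0):
    """Random real-surface descriptors (reality constraint enforced)."""
    rng = np.random.default_rng(seed)
    descs = []
    for _ in range(n):
        vec = rng.normal(size=3 * (L + 1) ** 2)
        descs.append(vector_to_descriptor(vec, L))
    return descs


class TestDescriptorStacking:
    def test_lossless_round_trip(self):
        desc = random_descriptors(1, L=5, seed=3)[0]
        again = vector_to_descriptor(descriptor_to_vector(desc), 5)
        assert np.abs(again.coefficients - desc.coefficients).max() == 0

    def test_reality_constraint_on_decode(self):
        desc = random_descriptors(1, L=3, seed=4)[0]
        for l in range(4):
            for m in range(1, l + 1):
                assert np.allclose(desc.get(l, -m),
                                   (-1) ** m * np.conj(desc.get(l, m)))


class TestDescriptorPCA:
    def test_full_rank_round_trip(self):
        descs = random_descriptors(8)
        model = cs.fit_descriptor_pca(descs, 7)
        for d in descs:
            rec = model.decode(model.encode(d))
            assert np.abs(rec.coefficients - d.coefficients).max() < 1e-8

    def test_k0_returns_mean(self):
        descs = random_descriptors(8)
        model = cs.fit_descriptor_pca(descs, 0)
        rec = model.decode(np.zeros(0))
        mean = np.mean([d.coefficients for d in descs], axis=0)
        assert np.abs(rec.coefficients - mean).max() < 1e-12

    def test_components_match_eigendecomposition_oracle(self):
        descs = random_descriptors(8, L=4, seed=9)
        X = np.stack([descriptor_to_vector(d) for d in descs])
        mu = X.mean(axis=0)
        C = (X - mu).T @ (X - mu) / (X.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        model = cs.fit_descriptor_pca(descs, 5)
        for j in range(5):
            assert abs(model.components[:, j] @ V[:, order[j]]) == \
                pytest.approx(1.0, abs=1e-8)

    def test_mixed_orders_rejected(self):
        descs = random_descriptors(3, L=4) + random_descriptors(1, L=5)
        with pytest.raises(ValueError, match="mixed"):
            cs.fit_descriptor_pca(descs, 2)

    def test_reported_dimension_counts_norm_param(self):
        model = cs.fit_descriptor_pca(random_descriptors(5), 3)
        assert model.reported_dimension == 4


class TestDecodeShape:
    def test_mean_latent_decodes_mean_shape(self):
        descs = random_descriptors(6)
        model = cs.fit_descriptor_pca(descs, 3)
        mesh = cs.decode_shape(model, np.zeros(3))
        mean_desc = model.decode(np.zeros(3))
        expected = cs.reconstruct_surface(mean_desc, model.recon_vertices)
        assert np.allclose(mesh.vertices, expected.vertices)

    def test_embed_decode_identity_on_subspace(self):
        descs = random_descriptors(6)
        model = cs.fit_descriptor_pca(descs, 4)
        z = np.array([1.0, -2.0, 0.5, 3.0])
        assert np.allclose(model.encode(model.decode(z)), z, atol=1e-9)

    def test_hausdorff_decreases_with_k(self, blob_pipeline):
        # population of rough blobs, reconstruction error vs latent dims
        descs = []
        meshes = []
        for s in range(8):
            vol = cs.generate_blob_3d(size=16, roughness=0.15, seed=s)
            mesh, mapping, _ = cs.parameterize_robust(
                vol, cs.RPDMOptions(working_order=8))
            meshes.append(mesh)
            descs.append(cs.fit_descriptor(mesh, mapping, 8))
        errors = []
        for k in (0, 3, 7):
            model = cs.fit_descriptor_pca(descs, k)
            errs = [cs.hausdorff_distance(
                m.vertices, cs.decode_shape(model, model.encode(d)).vertices)
                for m, d in zip(meshes, descs)]
            errors.append(np.mean(errs))
        assert errors[0] >= errors[1] >= errors[2]


class TestInterpolatePath:
    def test_formula_n2(self):
        z1, z2 = np.array([2.0, 0.0]), np.array([0.0, 4.0])
        path = cs.interpolate_path(z1, z2, 2)
        assert np.allclose(path[0], (z1 + z2) / 2)
        assert np.allclose(path[1], z1)

    def test_constant_when_equal(self):
        z = np.array([1.0, 2.0, 3.0])
        path = cs.interpolate_path(z, z, 5)
        assert np.allclose(path, z)

    def test_points_on_segment(self):
        rng = np.random.default_rng(0)
        z1, z2 = rng.normal(size=4), rng.normal(size=4)
        path = cs.interpolate_path(z1, z2, 7)
        direction = (z2 - z1) / np.linalg.norm(z2 - z1)
        for x in path:
            t = (x - z1) @ direction
            proj = z1 + t * direction
            assert np.linalg.norm(x - proj) < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cs.interpolate_path(np.zeros(2), np.zeros(3), 4)


class PointModel:
    """Decodes a latent point to a single 3D point (identity)."""

    def decode_points(self, z):
        return np.asarray(z, float).reshape(1, -1)


class TestEvolutionEnergy:
    def test_translation_family_attains_half_exactly(self):
        model = PointModel()
        z1, z2 = np.array([0.0, 0.0, 0.0]), np.array([6.0, 0.0, 0.0])
        res = cs.evolution_energy(model, z1, z2, N=10)
        assert res.normalized_energy == pytest.approx(0.5, abs=1e-12)

    def test_n1_energy_is_half_distance(self):
        model = PointModel()
        z1, z2 = np.array([1.0, 1.0, 0.0]), np.array([4.0, 5.0, 0.0])
        res = cs.evolution_energy(model, z1, z2, N=1)
        assert res.energy == pytest.approx(2.5)   # D/2 with D = 5
        assert res.normalized_energy == pytest.approx(0.5)

    def test_metric_lower_bound(self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 5)
        zs = [model.encode(o) for o in snl_outlines]
        for i, j in [(0, 1), (2, 5), (3, 9)]:
            res = cs.evolution_energy(model, zs[i], zs[j], N=6)
            assert res.normalized_energy >= 0.5 - 1e-9

    def test_degenerate_pair_rejected(self):
        model = PointModel()
        z = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="normalized energy undefined"):
            cs.evolution_energy(model, z, z + 1e-9, N=3)

    def test_path_endpoints_decode_to_source_and_target(self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 4)
        z1 = model.encode(snl_outlines[0])
        z2 = model.encode(snl_outlines[1])
        res = cs.evolution_energy(model, z1, z2, N=5)
        assert np.allclose(res.path[0], z2)
        assert np.allclose(res.path[-1], z1)


class TestJoint3DModel:
    def _paired_data(self, n=8, L=3):
        rng = np.random.default_rng(7)
        cells = random_descriptors(n, L=L, seed=1)
        nucs = random_descriptors(n, L=L, seed=2)
        pose = np.column_stack([rng.normal(size=(n, 3)) * 3,
                                rng.uniform(-0.5, 0.5, n)])
        return cells, nucs, pose

    @pytest.mark.parametrize("variant", ["separate", "joint"])
    def test_full_rank_round_trip(self, variant):
        cells, nucs, pose = self._paired_data()
        dims = 14 if variant == "separate" else 7
        model = cs.fit_joint_3d_model(cells, nucs, pose, dims, variant)
        code = model.encode(cells[0], nucs[0], pose[0])
        cell_mesh, nuc_mesh, pose_rec = model.decode(code)
        assert np.allclose(pose_rec, pose[0], atol=1e-6)
        expected = cs.reconstruct_surface(cells[0], model.recon_vertices)
        assert cs.hausdorff_distance(cell_mesh.vertices,
                                     expected.vertices) < 1e-6

    def test_independent_blocks_joint_close_to_separate(self):
        cells, nucs, pose = self._paired_data(n=12)
        err = {}
        for variant, dims in (("separate", 8), ("joint", 8)):
            model = cs.fit_joint_3d_model(cells, nucs, pose, dims, variant)
            tot = 0.0
            for c, n, p in zip(cells, nucs, pose):
                cell_mesh, _, _ = model.decode(model.encode(c, n, p))
                ref = cs.reconstruct_surface(c, model.recon_vertices)
                tot += cs.hausdorff_distance(cell_mesh.vertices, ref.vertices)
            err[variant] = tot / len(cells)
        assert abs(err["joint"] - err["separate"]) < \
            0.5 * max(err.values()) + 0.2

    def test_odd_dims_rejected_for_separate(self):
        cells, nucs, pose = self._paired_data()
        with pytest.raises(ValueError, match="even"):
            cs.fit_joint_3d_model(cells, nucs, pose, 7, "separate")
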