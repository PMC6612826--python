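"""Outline PCA, SCA and joint cell+nucleus models against dense oracles."""

import numpy as np
import pytest

import cellshape as cs
from cellshape.outline_models import relative_pose


def dense_pca_oracle(X: np.ndarray, k: int):
    """Eigendecomposition of the explicit covariance matrix."""
    mu = X.mean(axis=0)
    C = (X - mu).T @ (X - mu) / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return mu, V[:, order[:k]], w[order[:k]]


class TestOutlinePCA:
    def test_full_rank_recovery(self, snl_outlines):
        outlines = snl_outlines[:5]
        model = cs.fit_outline_pca(outlines, 4)
        for o in outlines:
            rec = model.decode(model.encode(o))
            assert cs.hausdorff_distance(o.points, rec.points) < 1e-6

    def test_k0_returns_mean(self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 0)
        rec = model.decode(np.zeros(0))
        assert np.allclose(rec.points.ravel(), model.mean)

    def test_components_match_covariance_oracle(self, tiny_outlines):
        X = np.stack([o.points.ravel() for o in tiny_outlines])
        model = cs.fit_outline_pca(tiny_outlines, 4)
        mu, V, w = dense_pca_oracle(X, 4)
        assert np.allclose(model.mean, mu, atol=1e-10)
        for j in range(4):
            dot = abs(model.components[:, j] @ V[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(model.explained_variance, w, rtol=1e-8)

    def test_encode_matches_oracle_projection(self, tiny_outlines):
        X = np.stack([o.points.ravel() for o in tiny_outlines])
        model = cs.fit_outline_pca(tiny_outlines, 3)
        mu, V, _ = dense_pca_oracle(X, 3)
        b = model.encode(tiny_outlines[0])
        b_oracle = V.T @ (X[0] - mu)
        assert np.allclose(np.abs(b), np.abs(b_oracle), atol=1e-8)

    def test_mean_encodes_to_zero_and_projection_idempotence(
            self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 5)
        mean_outline = cs.Outline2D(model.mean.reshape(-1, 2))
        assert np.allclose(model.encode(mean_outline), 0, atol=1e-9)
        b = np.array([3.0, -1.0, 0.5, 2.0, -0.7])
        assert np.allclose(model.encode(model.decode(b)), b, atol=1e-9)

    def test_decode_linearity(self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 4)
        b1, b2 = np.array([1.0, 2, 0, -1]), np.array([0.5, -1, 3, 2])
        lhs = model.decode(b1 + b2).points.ravel() - model.mean
        rhs = ((model.decode(b1).points.ravel() - model.mean)
               + (model.decode(b2).points.ravel() - model.mean))
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_reconstruction_error_non_increasing_in_k(self, snl_outlines):
        errors = []
        for k in (0, 2, 5, 9):
            model = cs.fit_outline_pca(snl_outlines, k)
            errors.append(np.mean([
                cs.hausdorff_distance(
                    o.points, model.decode(model.encode(o)).points)
                for o in snl_outlines]))
        assert all(errors[i + 1] <= errors[i] + 1e-9
                   for i in range(len(errors) - 1))

    def test_orthonormal_components_and_variance_order(self, snl_outlines):
        model = cs.fit_outline_pca(snl_outlines, 6)
        gram = model.components.T @ model.components
        assert np.allclose(gram, np.eye(6), atol=1e-10)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_errors(self, snl_outlines):
        with pytest.raises(ValueError, match="inconsistent"):
            cs.fit_outline_pca(
                [snl_outlines[0],
                 cs.Outline2D(np.random.default_rng(0).normal(size=(32, 2)))],
                1)
        with pytest.raises(ValueError, match="out of range"):
            cs.fit_outline_pca(snl_outlines, 50)
        model = cs.fit_outline_pca(snl_outlines, 3)
        with pytest.raises(ValueError, match="length"):
            model.decode(np.zeros(5))
        with pytest.raises(ValueError, match="points"):
            model.encode(cs.Outline2D(np.zeros((5, 2)) + np.arange(5)[:, None]))


class TestSCA:
    def test_c_matrix_psd_and_oracle_eigenvectors(self, tiny_outlines):
        pres = [cs.to_preshape(o) for o in tiny_outlines]
        n = pres[0].points.shape[0]
        C = np.zeros((n, n))
        for p in pres:
            x = p.points.T
            C += x.T @ x
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)
        model = cs.fit_sca(pres, 6)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:6]
        for j in range(6):
            assert abs(model.rotation[:, j] @ V[:, order[j]]) == \
                pytest.approx(1.0, abs=1e-8)

    def test_representation_unit_norm_and_full_rank_identity(
            self, tiny_outlines):
        pres = [cs.to_preshape(o) for o in tiny_outlines]
        n = pres[0].points.shape[0]
        model = cs.fit_sca(pres, n)
        for p in pres:
            b, rec = cs.sca_encode_decode(model, p)
            assert np.linalg.norm(b) == pytest.approx(1.0)
            assert np.allclose(rec.points, p.points, atol=1e-9)

    def test_half_rank_matches_dense_oracle(self, tiny_outlines):
        pres = [cs.to_preshape(o) for o in tiny_outlines]
        n = pres[0].points.shape[0]
        model = cs.fit_sca(pres, n // 2)
        x = pres[0].points.T
        R = model.rotation
        xr = x @ R
        expected = (xr / np.linalg.norm(xr)) @ R.T
        _, rec = cs.sca_encode_decode(model, pres[0])
        assert np.allclose(rec.points.T, expected, atol=1e-12)

    def test_identical_preshapes_reconstruct_exactly(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        o = cs.Outline2D(np.column_stack([3 * np.cos(t), np.sin(t)]))
        pres = [cs.to_preshape(o) for _ in range(4)]
        model = cs.fit_sca(pres, 2)
        _, rec = cs.sca_encode_decode(model, pres[0])
        assert np.allclose(rec.points, pres[0].points, atol=1e-9)

    def test_r_range_error(self, tiny_outlines):
        pres = [cs.to_preshape(o) for o in tiny_outlines]
        with pytest.raises(ValueError):
            cs.fit_sca(pres, pres[0].points.shape[0] + 1)


@pytest.fixture(scope="module")
def pair_outlines():
    pairs = [cs.generate_cell_nucleus_pair_2d(cs.PairParams(), s)
             for s in range(8)]
    cells = [cs.extract_outline(c, 96) for c, _ in pairs]
    nucs = [cs.extract_outline(n, 48) for _, n in pairs]
    return cells, nucs


class TestJointOutlineModel:
    @pytest.mark.parametrize("variant,method", [
        ("joint", "pca"), ("separate", "pca"), ("separate", "sca"),
    ])
    def test_full_rank_round_trip(self, pair_outlines, variant, method):
        cells, nucs = pair_outlines
        dims = (len(cells) - 1) if variant == "joint" else 2 * (len(cells) - 1)
        if method == "sca":
            dims = 4 * 48  # full rank for both SCA submodels
        model = cs.fit_joint_outline_model(cells, nucs, dims, variant, method)
        pose = relative_pose(cells[0], nucs[0])
        c2, n2 = model.decode(model.encode(cells[0], nucs[0]))
        aligned_c = cs.align_outline(cells[0])
        aligned_n = cs.align_outline(nucs[0])
        assert cs.hausdorff_distance(aligned_c.points, c2.points) < 1e-6
        pose2 = np.concatenate([n2.centroid() - c2.centroid(), [0]])
        assert np.allclose(pose2[:2], pose[:2], atol=1e-6)
        # nucleus shape itself round-trips (compare centered, unrotated)
        n2c = n2.points - n2.centroid()
        anc = aligned_n.points - aligned_n.centroid()
        assert n2c.shape == anc.shape

    def test_pose_features_round_trip_exactly(self, pair_outlines):
        cells, nucs = pair_outlines
        model = cs.fit_joint_outline_model(cells, nucs,
                                           2 * (len(cells) - 1),
                                           "separate", "pca")
        for c, n in zip(cells[:3], nucs[:3]):
            code = model.encode(c, n)
            assert np.allclose(code[-3:], relative_pose(c, n), atol=1e-12)

    def test_independent_blocks_joint_close_to_separate(self):
        # cell and nucleus variation constructed independently
        rng = np.random.default_rng(5)
        t_c = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        t_n = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        cells, nucs = [], []
        for _ in range(30):
            a = 40 + 6 * rng.normal()
            cells.append(cs.Outline2D(np.column_stack(
                [a * np.cos(t_c), 20 * np.sin(t_c)]) + 128))
            b = 12 + 2 * rng.normal()
            nucs.append(cs.Outline2D(np.column_stack(
                [b * np.cos(t_n), b * np.sin(t_n)]) + 128))
        sep = cs.fit_joint_outline_model(cells, nucs, 4, "separate", "pca")
        joi = cs.fit_joint_outline_model(cells, nucs, 4, "joint", "pca")

        def err(model):
            tot = 0.0
            for c, n in zip(cells, nucs):
                c2, n2 = model.decode(model.encode(c, n))
                tot += cs.hausdorff_distance(cs.align_outline(c).points,
                                             c2.points)
            return tot / len(cells)

        assert abs(err(sep) - err(joi)) < 0.5  # px, sampling tolerance

    def test_errors(self, pair_outlines):
        cells, nucs = pair_outlines
        with pytest.raises(ValueError, match="even"):
            cs.fit_joint_outline_model(cells, nucs, 5, "separate", "pca")
        with pytest.raises(ValueError, match="paired"):
            cs.fit_joint_outline_model(cells[:3], nucs, 4)
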