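"""Linear shape spaces over SPHARM descriptors and shape-space evolution.

Descriptors are stacked into real feature vectors (m >= 0 coefficients
only, interleaved Re/Im; negative orders are implied by the reality
constraint), reduced by PCA, and decoded back through the inverse
spherical harmonic transform.  Evolution between two embedded shapes is
modeled as linear interpolation in the latent space; its cost is the
deformation energy

    E(x1, x2) = (1 / 2N) * sum_i [ D(f(x_i), f(x1)) + D(f(x2), f(x_i)) ]

with ``x_i = [i x1 + (N - i) x2] / N`` and D the Hausdorff distance
between the decoded shapes in the original coordinate space.  The
normalized energy E / D(f(x1), f(x2)) is bounded below by 0.5 (triangle
inequality); a family of shapes differing only by translation attains the
bound exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .mesh_surface import SurfaceMesh
from .shape_core import hausdorff_distance
from .spharm import SPHARMDescriptor, coeff_index, reconstruct_surface

__all__ = [
    "ShapeSpaceModel",
    "JointShapeSpaceModel",
    "EvolutionResult",
    "descriptor_to_vector",
    "vector_to_descriptor",
    "fit_descriptor_pca",
    "embed",
    "decode_descriptor",
    "decode_shape",
    "interpolate_path",
    "evolution_energy",
    "fit_joint_3d_model",
]


def descriptor_to_vector(desc: SPHARMDescriptor) -> np.ndarray:
    """Real feature vector: per coordinate, per l: c_l0 (real), then
    (Re, Im) of c_lm for m = 1..l.  Lossless for real surfaces."""
    L = desc.max_order
    parts = []
    for row in desc.coefficients:
        for l in range(L + 1):
            parts.append(row[coeff_index(l, 0)].real)
            for m in range(1, l + 1):
                clm = row[coeff_index(l, m)]
                parts.append(clm.real)
                parts.append(clm.imag)
    return np.array(parts)


def vector_to_descriptor(vec: np.ndarray, max_order: int,
                         d: int = 3) -> SPHARMDescriptor:
    """Inverse of :func:`descriptor_to_vector` (reality constraint applied)."""
    L = max_order
    K = (L + 1) ** 2
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != d * K:
        raise ValueError(f"expected {d * K} features, got {vec.size}")
    coeffs = np.zeros((d, K), dtype=complex)
    j = 0
    for i in range(d):
        for l in range(L + 1):
            coeffs[i, coeff_index(l, 0)] = vec[j]
            j += 1
            for m in range(1, l + 1):
                clm = vec[j] + 1j * vec[j + 1]
                j += 2
                coeffs[i, coeff_index(l, m)] = clm
                coeffs[i, coeff_index(l, -m)] = (-1) ** m * np.conj(clm)
    return SPHARMDescriptor(coefficients=coeffs, max_order=L)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    if components.size == 0:
        return components
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


@dataclass
class ShapeSpaceModel:
    """PCA shape space over stacked SPHARM coefficient vectors.

    ``n_norm_params`` defaults to 1 (the alignment parameter), so the
    comparable model dimension is ``k + 1``.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    max_order: int
    d: int = 3
    n_norm_params: int = 1
    recon_vertices: int = 2562

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def reported_dimension(self) -> int:
        return self.k + self.n_norm_params

    def encode(self, desc: SPHARMDescriptor) -> np.ndarray:
        return embed(self, desc)

    def decode(self, z: np.ndarray) -> SPHARMDescriptor:
        return decode_descriptor(self, z)

    def decode_points(self, z: np.ndarray) -> np.ndarray:
        """Decoded shape as a point set in original coordinates."""
        return decode_shape(self, z).vertices


def fit_descriptor_pca(descriptors: list[SPHARMDescriptor],
                       k: int) -> ShapeSpaceModel:
    """PCA over real-stacked descriptor vectors, k latent dimensions."""
    if len(descriptors) < 2:
        raise ValueError("need at least 2 descriptors")
    L = descriptors[0].max_order
    if any(d.max_order != L for d in descriptors):
        orders = sorted({d.max_order for d in descriptors})
        raise ValueError(f"mixed maximum orders: {orders}")
    X = np.stack([descriptor_to_vector(d) for d in descriptors])
    max_k = min(len(descriptors) - 1, X.shape[1])
    if not 0 <= k <= max_k:
        raise ValueError(f"k={k} out of range [0, {max_k}]")
    mean = X.mean(axis=0)
    if k == 0:
        comps, ev = np.zeros((X.shape[1], 0)), np.zeros(0)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(X)
        comps = _fix_signs(pca.components_.T)
        ev = pca.explained_variance_
    return ShapeSpaceModel(mean=mean, components=comps,
                           explained_variance=ev, max_order=L,
                           d=descriptors[0].d)


def embed(model: ShapeSpaceModel, desc: SPHARMDescriptor) -> np.ndarray:
    if desc.max_order != model.max_order:
        raise ValueError(
            f"descriptor order {desc.max_order} != model order "
            f"{model.max_order}")
    return model.components.T @ (descriptor_to_vector(desc) - model.mean)


def decode_descriptor(model: ShapeSpaceModel, z: np.ndarray
                      ) -> SPHARMDescriptor:
    z = np.asarray(z, dtype=float).ravel()
    if z.size != model.k:
        raise ValueError(f"latent vector length {z.size}, expected {model.k}")
    vec = model.components @ z + model.mean
    return vector_to_descriptor(vec, model.max_order, model.d)


def decode_shape(model: ShapeSpaceModel, z: np.ndarray) -> SurfaceMesh:
    """Latent point -> descriptor -> evenly sampled surface mesh."""
    return reconstruct_surface(decode_descriptor(model, z),
                               model.recon_vertices)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    """A linear evolution path and its deformation energy."""

    path: np.ndarray              # (N + 2, k): z2, interior points, z1 order
    energy: float                 # pixels
    normalized_energy: float      # dimensionless, >= 0.5
    n_steps: int


def interpolate_path(z1: np.ndarray, z2: np.ndarray, N: int) -> np.ndarray:
    """Discrete path points ``x_i = [i z1 + (N - i) z2] / N`` for i = 1..N.

    Note the convention: x_N equals z1 and the path approaches (but does
    not include) z2 as i decreases to 1; callers rendering the morph
    should prepend z2 themselves (see :func:`evolution_energy`).
    """
    z1 = np.asarray(z1, dtype=float).ravel()
    z2 = np.asarray(z2, dtype=float).ravel()
    if z1.shape != z2.shape:
        raise ValueError("latent points have different dimensions")
    if N < 1:
        raise ValueError("N must be >= 1")
    i = np.arange(1, N + 1)[:, None]
    return (i * z1[None, :] + (N - i) * z2[None, :]) / N


def evolution_energy(model, z1: np.ndarray, z2: np.ndarray, N: int = 10,
                     eps: float = 1e-6) -> EvolutionResult:
    """Deformation energy of the linear path from z1 toward z2.

    ``model`` must expose ``decode_points(z) -> point set``; distances are
    Hausdorff distances between decoded shapes in the original coordinate
    space.  Raises if the endpoints decode to shapes closer than ``eps``
    (the normalization would be undefined).
    """
    z1 = np.asarray(z1, dtype=float).ravel()
    z2 = np.asarray(z2, dtype=float).ravel()
    f1 = model.decode_points(z1)
    f2 = model.decode_points(z2)
    D12 = hausdorff_distance(f1, f2)
    if D12 <= eps:
        raise ValueError(
            f"endpoint shapes are {D12:.3g} apart (<= eps={eps}); "
            "normalized energy undefined")
    path = interpolate_path(z1, z2, N)
    total = 0.0
    for x in path:
        fx = model.decode_points(x)
        total += hausdorff_distance(fx, f1) + hausdorff_distance(f2, fx)
    energy = total / (2.0 * N)
    full_path = np.vstack([z2[None, :], path])
    return EvolutionResult(path=full_path, energy=energy,
                           normalized_energy=energy / D12, n_steps=N)


# ---------------------------------------------------------------------------
# Joint 3D cell + nucleus modeling
# ---------------------------------------------------------------------------

@dataclass
class JointShapeSpaceModel:
    """Joint model of paired cell and nucleus SPHARM descriptors.

    ``separate``: one descriptor-PCA per structure with half the latent
    dimensions each; the relative pose (3D nuclear center offset + Z
    angle) rides along uncompressed.  ``joint``: a single PCA over the
    concatenated coefficient vectors plus the z-scored pose features.
    """

    variant: str
    total_dims: int
    max_order: int
    cell_model: ShapeSpaceModel = None
    nucleus_model: ShapeSpaceModel = None
    joint_mean: np.ndarray = None
    joint_components: np.ndarray = None
    pose_mean: np.ndarray = field(default_factory=lambda: np.zeros(4))
    pose_std: np.ndarray = field(default_factory=lambda: np.ones(4))
    recon_vertices: int = 2562

    def encode(self, cell_desc: SPHARMDescriptor,
               nuc_desc: SPHARMDescriptor,
               pose: np.ndarray) -> np.ndarray:
        pose = np.asarray(pose, dtype=float).ravel()
        if self.variant == "separate":
            return np.concatenate([
                embed(self.cell_model, cell_desc),
                embed(self.nucleus_model, nuc_desc),
                pose,
            ])
        z = (pose - self.pose_mean) / self.pose_std
        vec = np.concatenate([descriptor_to_vector(cell_desc),
                              descriptor_to_vector(nuc_desc), z])
        return self.joint_components.T @ (vec - self.joint_mean)

    def decode(self, code: np.ndarray
               ) -> tuple[SurfaceMesh, SurfaceMesh, np.ndarray]:
        """Returns (cell mesh, nucleus mesh posed inside the cell, pose)."""
        code = np.asarray(code, dtype=float).ravel()
        K = (self.max_order + 1) ** 2 * 3
        if self.variant == "separate":
            kc, kn = self.cell_model.k, self.nucleus_model.k
            cell_desc = decode_descriptor(self.cell_model, code[:kc])
            nuc_desc = decode_descriptor(self.nucleus_model,
                                         code[kc:kc + kn])
            pose = code[kc + kn:]
        else:
            k = self.joint_components.shape[1]
            vec = self.joint_components @ code[:k] + self.joint_mean
            cell_desc = vector_to_descriptor(vec[:K], self.max_order)
            nuc_desc = vector_to_descriptor(vec[K:2 * K], self.max_order)
            pose = vec[2 * K:] * self.pose_std + self.pose_mean
        cell = reconstruct_surface(cell_desc, self.recon_vertices)
        nuc = reconstruct_surface(nuc_desc, self.recon_vertices)
        c, s = np.cos(pose[3]), np.sin(pose[3])
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        centered = nuc.vertices - nuc.vertices.mean(axis=0)
        posed = centered @ R.T + cell.vertices.mean(axis=0) + pose[:3]
        return cell, SurfaceMesh(vertices=posed, faces=nuc.faces), pose


def fit_joint_3d_model(cell_descs: list[SPHARMDescriptor],
                       nuc_descs: list[SPHARMDescriptor],
                       rel_pose: np.ndarray, total_dims: int,
                       variant: str = "separate") -> JointShapeSpaceModel:
    """Joint or separate shape space for paired cell/nucleus descriptors.

    ``rel_pose`` is (n, 4): nuclear center offset (x, y, z) and Z-axis
    orientation angle relative to the cell.
    """
    if len(cell_descs) != len(nuc_descs):
        raise ValueError("cell and nucleus descriptor lists must be paired")
    rel_pose = np.atleast_2d(np.asarray(rel_pose, dtype=float))
    if rel_pose.shape != (len(cell_descs), 4):
        raise ValueError("rel_pose must be (n, 4)")
    if variant not in ("separate", "joint"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "separate" and total_dims % 2:
        raise ValueError("separate variant requires an even total_dims")
    L = cell_descs[0].max_order
    model = JointShapeSpaceModel(
        variant=variant, total_dims=total_dims, max_order=L,
        pose_mean=rel_pose.mean(axis=0),
        pose_std=np.where(rel_pose.std(axis=0) > 1e-12,
                          rel_pose.std(axis=0), 1.0))
    if variant == "separate":
        model.cell_model = fit_descriptor_pca(cell_descs, total_dims // 2)
        model.nucleus_model = fit_descriptor_pca(nuc_descs, total_dims // 2)
    else:
        z = (rel_pose - model.pose_mean) / model.pose_std
        X = np.hstack([
            np.stack([descriptor_to_vector(d) for d in cell_descs]),
            np.stack([descriptor_to_vector(d) for d in nuc_descs]),
            z,
        ])
        k = min(total_dims, len(cell_descs) - 1, X.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(X)
        model.joint_mean = X.mean(axis=0)
        model.joint_components = _fix_signs(pca.components_.T)
    return model
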