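"""2D generative shape models over outline landmarks.

Two linear families:

* **Outline PCA** — PCA over vectorized, aligned outline coordinates.  A
  shape ``x`` (2 x n landmark matrix) is encoded as
  ``b = U_k^T (vec(x) - mu)`` and decoded as ``x_hat = U_k b + mu``.
* **SCA** (shape component analysis) — operates on preshapes (location and
  scale removed).  The n x n matrix ``C = sum_j x_j^T x_j`` is accumulated
  over training preshapes, its leading ``r`` eigenvectors form ``R``, and a
  preshape is represented as ``b_o = x R / ||x R||_F`` with reconstruction
  ``x_hat = b_o R^T``.  The representation has unit Frobenius norm by
  construction; the removed size is an explicit normalization parameter.

Joint cell+nucleus variants concatenate the per-shape features and add the
relative pose of the nucleus within the cell (center offset + orientation).

Vectorization layout: landmarks stored as (n, 2) arrays are flattened
row-major, i.e. ``(x1, y1, x2, y2, ...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

from .shape_core import Outline2D, Preshape, align_outline, to_preshape

__all__ = [
    "OutlinePCAModel",
    "SCAModel",
    "JointOutlineModel",
    "fit_outline_pca",
    "pca_encode",
    "pca_decode",
    "fit_sca",
    "sca_encode_decode",
    "fit_joint_outline_model",
    "relative_pose",
]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if components.size == 0:
        return components
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


@dataclass
class OutlinePCAModel:
    """Linear outline shape space: mean + orthonormal principal directions.

    ``n_norm_params`` counts the explicit normalization parameters (one
    alignment parameter by default) so that the comparable model dimension
    is ``k + n_norm_params``.
    """

    mean: np.ndarray          # (n*d,)
    components: np.ndarray    # (n*d, k), orthonormal columns
    explained_variance: np.ndarray
    n_points: int
    d: int = 2
    n_norm_params: int = 1

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def reported_dimension(self) -> int:
        return self.k + self.n_norm_params

    def encode(self, outline: Outline2D) -> np.ndarray:
        return pca_encode(self, outline)

    def decode(self, b: np.ndarray) -> Outline2D:
        return pca_decode(self, b)

    def decode_points(self, b: np.ndarray) -> np.ndarray:
        """Decoded landmark point set (for evolution-energy computations)."""
        return pca_decode(self, b).points


def fit_outline_pca(outlines: list[Outline2D], k: int) -> OutlinePCAModel:
    """Fit outline PCA on aligned outlines with ``k`` latent dimensions."""
    if len(outlines) < 2:
        raise ValueError("need at least 2 outlines")
    n_points = outlines[0].n_points
    if any(o.n_points != n_points for o in outlines):
        counts = sorted({o.n_points for o in outlines})
        raise ValueError(f"inconsistent n_points across outlines: {counts}")
    X = np.stack([o.points.ravel() for o in outlines])
    max_k = min(len(outlines) - 1, X.shape[1])
    if not 0 <= k <= max_k:
        raise ValueError(f"k={k} out of range [0, {max_k}] for this data")
    mean = X.mean(axis=0)
    if k == 0:
        comps = np.zeros((X.shape[1], 0))
        ev = np.zeros(0)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(X)
        comps = _fix_signs(pca.components_.T)
        ev = pca.explained_variance_
    return OutlinePCAModel(mean=mean, components=comps,
                           explained_variance=ev, n_points=n_points)


def _check_layout(model: OutlinePCAModel, outline: Outline2D) -> None:
    if outline.n_points != model.n_points:
        raise ValueError(
            f"outline has {outline.n_points} points, model expects {model.n_points}"
        )


def pca_encode(model: OutlinePCAModel, outline: Outline2D) -> np.ndarray:
    """``b = U_k^T (vec(x) - mu)``."""
    _check_layout(model, outline)
    return model.components.T @ (outline.points.ravel() - model.mean)


def pca_decode(model: OutlinePCAModel, b: np.ndarray) -> Outline2D:
    """``x_hat = U_k b + mu``, reshaped back to landmarks."""
    b = np.asarray(b, dtype=float).ravel()
    if b.size != model.k:
        raise ValueError(f"latent vector has length {b.size}, expected {model.k}")
    vec = model.components @ b + model.mean
    return Outline2D(vec.reshape(model.n_points, model.d))


@dataclass
class SCAModel:
    """Shape component analysis model.

    ``rotation`` holds the first ``r`` eigenvectors of ``C = sum_j x_j^T x_j``
    as columns.  ``n_norm_params`` is 1: the explicit size parameter removed
    when forming preshapes.
    """

    rotation: np.ndarray      # (n, r)
    eigenvalues: np.ndarray   # (r,), non-increasing
    n_points: int
    d: int = 2
    n_norm_params: int = 1

    @property
    def r(self) -> int:
        return self.rotation.shape[1]

    def encode_decode(self, preshape: Preshape):
        return sca_encode_decode(self, preshape)


def fit_sca(preshapes: list[Preshape], r: int) -> SCAModel:
    """Accumulate ``C = sum_j x_j^T x_j`` and keep its top-``r`` eigenvectors."""
    if len(preshapes) < 2:
        raise ValueError("need at least 2 preshapes")
    n = preshapes[0].points.shape[0]
    if any(p.points.shape[0] != n for p in preshapes):
        raise ValueError("preshapes have inconsistent landmark counts")
    if not 1 <= r <= n:
        raise ValueError(f"r={r} must be in [1, {n}]")
    C = np.zeros((n, n))
    for p in preshapes:
        x = p.points.T  # d x n, as in the model definition
        C += x.T @ x
    w, V = linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order][:r], V[:, order][:, :r]
    return SCAModel(rotation=_fix_signs(V), eigenvalues=w, n_points=n)


def sca_encode_decode(model: SCAModel, preshape: Preshape):
    """Representation ``b_o = x R / ||x R||_F`` and reconstruction ``b_o R^T``.

    Returns ``(b_o, reconstruction)`` where ``b_o`` is a d x r matrix with
    unit Frobenius norm and the reconstruction is a :class:`Preshape` with
    the input's stored size and location.
    """
    x = preshape.points.T  # d x n
    if x.shape[1] != model.n_points:
        raise ValueError("preshape landmark count does not match model")
    xr = x @ model.rotation
    norm = np.linalg.norm(xr)
    if norm < 1e-300:
        raise ValueError("preshape is orthogonal to the retained eigenspace")
    b_o = xr / norm
    x_hat = b_o @ model.rotation.T
    recon = Preshape(points=x_hat.T, scale=preshape.scale,
                     center=preshape.center)
    return b_o, recon


# ---------------------------------------------------------------------------
# Joint cell + nucleus modeling
# ---------------------------------------------------------------------------

def relative_pose(cell: Outline2D, nucleus: Outline2D) -> np.ndarray:
    """Nuclear pose relative to the cell: (dx, dy, dtheta).

    Center offset is the nuclear centroid minus the cell centroid;
    orientation is the nuclear second-moment major-axis angle minus the
    cell's, wrapped to (-pi/2, pi/2] (axes are head-less).
    """
    offset = nucleus.centroid() - cell.centroid()

    def _axis_angle(o: Outline2D) -> float:
        p = o.points - o.points.mean(axis=0)
        mu20 = np.mean(p[:, 0] ** 2)
        mu02 = np.mean(p[:, 1] ** 2)
        mu11 = np.mean(p[:, 0] * p[:, 1])
        return 0.5 * np.arctan2(2 * mu11, mu20 - mu02)

    dtheta = _axis_angle(nucleus) - _axis_angle(cell)
    dtheta = (dtheta + np.pi / 2) % np.pi - np.pi / 2
    return np.array([offset[0], offset[1], dtheta])


@dataclass
class JointOutlineModel:
    """Joint model of paired cell and nuclear outlines.

    variant ``separate``: one submodel per structure, half the latent
    dimensions each; the relative pose travels alongside the code,
    uncompressed.  variant ``joint``: a single PCA over the concatenated
    cell+nucleus vectors plus the three z-scored relative-pose features.
    ``method`` selects PCA (aligned outlines) or SCA (preshapes; the joint
    SCA concatenates landmark columns and keeps pose features explicit).
    """

    variant: str
    method: str
    total_dims: int
    cell_model: object = None
    nucleus_model: object = None
    joint_model: object = None
    pose_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pose_std: np.ndarray = field(default_factory=lambda: np.ones(3))
    n_cell_points: int = 0
    n_nuc_points: int = 0

    # -- encoding -----------------------------------------------------------
    def encode(self, cell: Outline2D, nucleus: Outline2D) -> np.ndarray:
        pose = relative_pose(cell, nucleus)
        cell_a = align_outline(cell)
        nuc_a = align_outline(nucleus)
        if self.method == "pca":
            if self.variant == "separate":
                bc = pca_encode(self.cell_model, cell_a)
                bn = pca_encode(self.nucleus_model, nuc_a)
                return np.concatenate([bc, bn, pose])
            z = (pose - self.pose_mean) / self.pose_std
            vec = np.concatenate([cell_a.points.ravel(),
                                  nuc_a.points.ravel(), z])
            return self.joint_model.components.T @ (vec - self.joint_model.mean)
        # SCA: encode preshapes
        pc, pn = to_preshape(cell_a), to_preshape(nuc_a)
        if self.variant == "separate":
            bc, _ = sca_encode_decode(self.cell_model, pc)
            bn, _ = sca_encode_decode(self.nucleus_model, pn)
            return np.concatenate([bc.ravel(), bn.ravel(),
                                   [pc.scale, pn.scale], pose])
        joint_pre = Preshape(
            points=np.vstack([pc.points, pn.points]), scale=1.0)
        b, _ = sca_encode_decode(self.joint_model, joint_pre)
        return np.concatenate([b.ravel(), [pc.scale, pn.scale], pose])

    # -- decoding -----------------------------------------------------------
    def decode(self, code: np.ndarray) -> tuple[Outline2D, Outline2D]:
        code = np.asarray(code, dtype=float).ravel()
        if self.method == "pca":
            if self.variant == "separate":
                kc = self.cell_model.k
                kn = self.nucleus_model.k
                bc, bn, pose = code[:kc], code[kc:kc + kn], code[kc + kn:]
                cell = pca_decode(self.cell_model, bc)
                nuc = pca_decode(self.nucleus_model, bn)
            else:
                vec = self.joint_model.components @ code[:self.joint_model.k] \
                    + self.joint_model.mean
                nc, nn = self.n_cell_points, self.n_nuc_points
                cell = Outline2D(vec[:2 * nc].reshape(nc, 2))
                nuc = Outline2D(vec[2 * nc:2 * (nc + nn)].reshape(nn, 2))
                pose = vec[2 * (nc + nn):] * self.pose_std + self.pose_mean
        else:
            nc, nn = self.n_cell_points, self.n_nuc_points
            if self.variant == "separate":
                rc = self.cell_model.r
                rn = self.nucleus_model.r
                bc = code[:2 * rc].reshape(2, rc)
                bn = code[2 * rc:2 * (rc + rn)].reshape(2, rn)
                rest = code[2 * (rc + rn):]
                cell_pts = (bc @ self.cell_model.rotation.T).T
                nuc_pts = (bn @ self.nucleus_model.rotation.T).T
            else:
                r = self.joint_model.r
                b = code[:2 * r].reshape(2, r)
                rest = code[2 * r:]
                pts = (b @ self.joint_model.rotation.T).T
                cell_pts, nuc_pts = pts[:nc], pts[nc:]
            sc, sn = rest[0], rest[1]
            pose = rest[2:]
            cell = Outline2D(cell_pts * sc)
            nuc = Outline2D(nuc_pts * sn)
        # position the nucleus relative to the cell
        c, s = np.cos(pose[2]), np.sin(pose[2])
        rot = np.array([[c, -s], [s, c]])
        nuc_pts = (nuc.points - nuc.points.mean(axis=0)) @ rot.T
        nuc = Outline2D(nuc_pts + cell.centroid() + pose[:2])
        return cell, nuc


def fit_joint_outline_model(cells: list[Outline2D], nuclei: list[Outline2D],
                            total_dims: int, variant: str = "separate",
                            method: str = "pca") -> JointOutlineModel:
    """Fit a joint cell+nucleus outline model.

    For ``separate`` models half the dimensions go to the cell and half to
    the nucleus; ``joint`` models learn one embedding of the concatenated
    features.  Relative pose (center offset and orientation of the nucleus
    within the cell) is always carried as explicit features.
    """
    if len(cells) != len(nuclei):
        raise ValueError("cells and nuclei must be paired lists")
    if variant not in ("separate", "joint"):
        raise ValueError(f"unknown variant {variant!r}")
    if method not in ("pca", "sca"):
        raise ValueError(f"unknown method {method!r}")
    if total_dims < 2:
        raise ValueError("total_dims must be >= 2")
    if variant == "separate" and total_dims % 2:
        raise ValueError("separate variant requires an even total_dims")

    poses = np.stack([relative_pose(c, n) for c, n in zip(cells, nuclei)])
    cells_a = [align_outline(c) for c in cells]
    nuclei_a = [align_outline(n) for n in nuclei]
    model = JointOutlineModel(
        variant=variant, method=method, total_dims=total_dims,
        n_cell_points=cells_a[0].n_points, n_nuc_points=nuclei_a[0].n_points,
        pose_mean=poses.mean(axis=0),
        pose_std=np.where(poses.std(axis=0) > 1e-12, poses.std(axis=0), 1.0),
    )
    if method == "pca":
        if variant == "separate":
            model.cell_model = fit_outline_pca(cells_a, total_dims // 2)
            model.nucleus_model = fit_outline_pca(nuclei_a, total_dims // 2)
        else:
            z = (poses - model.pose_mean) / model.pose_std
            X = np.hstack([
                np.stack([o.points.ravel() for o in cells_a]),
                np.stack([o.points.ravel() for o in nuclei_a]),
                z,
            ])
            max_k = min(len(cells) - 1, X.shape[1])
            k = min(total_dims, max_k)
            pca = PCA(n_components=k, svd_solver="full")
            pca.fit(X)
            model.joint_model = OutlinePCAModel(
                mean=X.mean(axis=0), components=_fix_signs(pca.components_.T),
                explained_variance=pca.explained_variance_,
                n_points=X.shape[1] // 2, d=2)
    else:
        pre_c = [to_preshape(o) for o in cells_a]
        pre_n = [to_preshape(o) for o in nuclei_a]
        if variant == "separate":
            # b_o is d x r, so r latent columns give 2r numbers per shape
            r = max(1, total_dims // 4)
            model.cell_model = fit_sca(pre_c, r)
            model.nucleus_model = fit_sca(pre_n, r)
        else:
            joint_pre = [
                Preshape(points=np.vstack([pc.points, pn.points]), scale=1.0)
                for pc, pn in zip(pre_c, pre_n)
            ]
            model.joint_model = fit_sca(joint_pre, max(1, total_dims // 2))
    return model
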