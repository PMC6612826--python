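"""Spherical harmonic shape descriptors.

A genus-0 surface with a spherical parameterization is expanded as

    r(theta, phi) = sum_{l=0}^{L} sum_{m=-l}^{l} c_lm Y_lm(theta, phi)

with one complex coefficient vector per spatial coordinate (x, y, z).
``Y_lm`` is the standard orthonormal basis with Condon-Shortley phase
(scipy's convention).  Coefficients are fitted by (optionally area-
weighted) least squares over the mesh vertices; surfaces are reconstructed
by evaluating the expansion on a quasi-uniform subdivided icosahedron.

The first-order-ellipsoid (FOE) alignment rotates a shape about the Z axis
so the major axis of its degree-1 ellipsoid lies in the XZ plane, then
resolves the remaining 180-degree ambiguity by requiring non-negative
x-skewness of the XY projection.  Cells attached to a substrate are only
rotated in-plane, so Z is the only rotation axis used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special as special
import trimesh

from ._sphere import SphericalMap, quad_signed_areas
from .mesh_surface import SurfaceMesh

__all__ = [
    "SPHARMDescriptor",
    "spherical_harmonic",
    "complex_basis",
    "fit_descriptor",
    "reconstruct_surface",
    "foe_align",
]


def coeff_index(l: int, m: int) -> int:
    """Position of (l, m) in the packed coefficient layout l*l + l + m."""
    return l * l + l + m


def spherical_harmonic(l: int, m: int, theta, phi) -> np.ndarray:
    """Orthonormal ``Y_lm`` with Condon-Shortley phase, vectorized."""
    if l < 0 or abs(m) > l:
        raise ValueError(f"invalid degree/order (l={l}, m={m})")
    return special.sph_harm_y(l, m, np.asarray(theta), np.asarray(phi))


def complex_basis(L: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """(N, (L+1)^2) matrix of Y_lm values in packed (l, m) layout."""
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    # (L+1, 2L+1, N) with the m axis wrap-indexed (m and m-2L-1 coincide)
    all_y = special.sph_harm_y_all(L, L, theta, phi)
    B = np.empty((theta.size, (L + 1) ** 2), dtype=complex)
    for l in range(L + 1):
        for m in range(-l, l + 1):
            B[:, coeff_index(l, m)] = all_y[l, m]
    return B


@dataclass
class SPHARMDescriptor:
    """Complex SPHARM coefficients, one row per spatial coordinate.

    ``coefficients`` has shape (d, (L+1)^2) with the packed layout
    ``l*l + l + m``; for real surfaces the reality constraint
    ``c_{l,-m} = (-1)^m conj(c_lm)`` holds.
    """

    coefficients: np.ndarray
    max_order: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        expected = (self.max_order + 1) ** 2
        if self.coefficients.shape[-1] != expected:
            raise ValueError(
                f"expected {expected} coefficients per coordinate, "
                f"got {self.coefficients.shape[-1]}"
            )

    @property
    def d(self) -> int:
        return self.coefficients.shape[0]

    def get(self, l: int, m: int) -> np.ndarray:
        return self.coefficients[:, coeff_index(l, m)]

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Evaluate the expansion; returns (N, d) real coordinates."""
        B = complex_basis(self.max_order, theta, phi)
        values = B @ self.coefficients.T
        return values.real


def _real_design_matrix(L: int, theta: np.ndarray, phi: np.ndarray
                        ) -> np.ndarray:
    """Real design matrix whose coefficients are Re/Im of c_lm, m >= 0.

    For a real-valued expansion, c_{l,-m} is determined by c_lm, and
    ``f = c_l0 Y_l0 + sum_{m>0} 2 [Re(c_lm) Re(Y_lm) - Im(c_lm) Im(Y_lm)]``.
    Column order per l: m=0, then (Re, Im) pairs for m = 1..l.
    """
    B = complex_basis(L, theta, phi)
    cols = []
    for l in range(L + 1):
        cols.append(B[:, coeff_index(l, 0)].real)
        for m in range(1, l + 1):
            y = B[:, coeff_index(l, m)]
            cols.append(2.0 * y.real)
            cols.append(-2.0 * y.imag)
    return np.column_stack(cols)


def _real_to_complex(a: np.ndarray, L: int) -> np.ndarray:
    """Pack real fit coefficients (d, (L+1)^2 real) into complex c_lm."""
    d = a.shape[0]
    c = np.zeros((d, (L + 1) ** 2), dtype=complex)
    j = 0
    for l in range(L + 1):
        c[:, coeff_index(l, 0)] = a[:, j]
        j += 1
        for m in range(1, l + 1):
            clm = a[:, j] + 1j * a[:, j + 1]
            j += 2
            c[:, coeff_index(l, m)] = clm
            c[:, coeff_index(l, -m)] = (-1) ** m * np.conj(clm)
    return c


def vertex_areas(mapping: SphericalMap, mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex weights: 1/4 of each incident spherical quad area.

    Approximates the spherical Voronoi cell area so the discrete least
    squares approximates the continuous inner product.
    """
    areas = np.abs(quad_signed_areas(mapping.theta, mapping.phi, mesh.faces))
    w = np.zeros(mesh.n_vertices)
    np.add.at(w, mesh.faces.ravel(),
              np.repeat(areas / mesh.faces.shape[1], mesh.faces.shape[1]))
    return w


def fit_descriptor(mesh: SurfaceMesh, mapping: SphericalMap, L: int,
                   weighted: bool = True) -> SPHARMDescriptor:
    """Least-squares SPHARM fit of the mesh coordinates over the basis.

    Solves, per spatial coordinate, ``min sum_i w_i |sum c_lm Y_lm - x_i|^2``
    with w the approximate spherical Voronoi areas (or 1 when
    ``weighted=False``).  The reality constraint is enforced exactly by
    fitting in the real harmonic parameterization.
    """
    V = mesh.n_vertices
    if mapping.theta.shape[0] != V:
        raise ValueError("spherical map does not cover all mesh vertices")
    K = (L + 1) ** 2
    if K > V:
        raise ValueError(
            f"(L+1)^2 = {K} basis functions exceed {V} vertices; lower L"
        )
    A = _real_design_matrix(L, mapping.theta, mapping.phi)
    X = mesh.vertices
    if weighted:
        w = vertex_areas(mapping, mesh)
        w = np.maximum(w, 1e-12 * w.max())
    else:
        w = np.ones(V)
    Aw = A * w[:, None]
    G = A.T @ Aw
    rhs = Aw.T @ X
    # tiny Tikhonov term guards against exact rank loss from duplicate angles
    eigs = np.linalg.eigvalsh(G)
    if eigs[-1] <= 0 or eigs[0] / eigs[-1] < 1e-14:
        raise np.linalg.LinAlgError(
            f"rank-deficient basis matrix at L={L}; lower L or refine the map"
        )
    a = np.linalg.solve(G, rhs).T  # (d, K real coefficients)
    return SPHARMDescriptor(coefficients=_real_to_complex(a, L), max_order=L,
                            metadata={"weighted": weighted, "n_vertices": V})


def sphere_sampling(n_vertices: int) -> trimesh.Trimesh:
    """Smallest subdivided icosahedron with at least ``n_vertices`` vertices."""
    if n_vertices < 12:
        raise ValueError("n_vertices must be >= 12")
    subdiv = 0
    while 10 * 4 ** subdiv + 2 < n_vertices:
        subdiv += 1
    return trimesh.creation.icosphere(subdivisions=subdiv)


def reconstruct_surface(desc: SPHARMDescriptor, n_vertices: int = 2562
                        ) -> SurfaceMesh:
    """Evaluate the expansion on a quasi-uniform sphere sampling.

    Returns a triangle mesh whose vertices are evenly spread in parameter
    space, hence roughly evenly spaced on the reconstructed surface.
    """
    sphere = sphere_sampling(n_vertices)
    v = np.asarray(sphere.vertices)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * np.pi)
    B = complex_basis(desc.max_order, theta, phi)
    coords = B @ desc.coefficients.T
    return SurfaceMesh(vertices=coords.real,
                       faces=np.asarray(sphere.faces))


def _rotate_z(desc: SPHARMDescriptor, alpha: float) -> SPHARMDescriptor:
    """Rigid rotation of the shape about the Z axis through the origin.

    Acts on the coordinate channels: each (l, m) coefficient triple is an
    (x, y, z) vector and rotates like one, the degree-0 translation
    included, so differently-rotated copies of one shape align to the same
    descriptor.  Exact and unitary per degree; the parameterization is
    left untouched.  (For shapes centered at the origin the translation
    block is ~0 and is effectively unaffected.)
    """
    c, s = np.cos(alpha), np.sin(alpha)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return SPHARMDescriptor(coefficients=R @ desc.coefficients,
                            max_order=desc.max_order,
                            metadata=dict(desc.metadata))


def first_order_ellipsoid(desc: SPHARMDescriptor) -> np.ndarray:
    """3x3 real matrix M mapping the unit sphere to the degree-1 ellipsoid.

    ``r_1(theta, phi) = M n(theta, phi)`` with n the unit normal; columns
    follow from the degree-1 coefficients.
    """
    k = np.sqrt(3.0 / (8.0 * np.pi))
    c_m1 = desc.get(1, -1)
    c_0 = desc.get(1, 0)
    c_p1 = desc.get(1, 1)
    col_x = k * (c_m1 - c_p1)
    col_y = -1j * k * (c_m1 + c_p1)
    col_z = np.sqrt(3.0 / (4.0 * np.pi)) * c_0
    return np.stack([col_x, col_y, col_z], axis=1).real


def _xy_skewness(desc: SPHARMDescriptor, n_vertices: int = 642) -> float:
    """Third standardized moment of x over the reconstructed surface."""
    mesh = reconstruct_surface(desc, n_vertices)
    x = mesh.vertices[:, 0]
    x = x - x.mean()
    std = x.std()
    if std == 0:
        return 0.0
    return float(np.mean(x ** 3) / std ** 3)


def foe_align(desc: SPHARMDescriptor, degeneracy_tol: float = 1e-6,
              return_info: bool = False):
    """First-order-ellipsoid alignment with Z-only rotation.

    The degree-1 ellipsoid's major axis is rotated into the XZ plane by a
    rotation about Z; if the x-skewness of the XY projection is then
    negative, a further 180-degree Z rotation is applied.  The rotation is
    rigid about the Z axis through the origin (translation rotates too);
    center shapes first if the translation must be preserved verbatim.

    A descriptor whose FOE is spherical (or whose major axis is along Z)
    to within ``degeneracy_tol`` is returned unrotated, flagged degenerate.
    """
    if desc.max_order < 1:
        raise ValueError("FOE alignment needs max_order >= 1")
    M = first_order_ellipsoid(desc)
    U, S, _ = np.linalg.svd(M)
    major = U[:, 0]
    xy = np.hypot(major[0], major[1])
    scale = S[0] if S[0] > 0 else 1.0
    degenerate = (S[0] - S[1]) / scale < degeneracy_tol or xy / 1.0 < degeneracy_tol
    info = {"degenerate": bool(degenerate), "rotation": 0.0, "flipped": False}
    if degenerate:
        out = desc
    else:
        alpha = -np.arctan2(major[1], major[0])
        out = _rotate_z(desc, alpha)
        info["rotation"] = float(alpha)
        if _xy_skewness(out) < 0:
            out = _rotate_z(out, np.pi)
            info["flipped"] = True
    if return_info:
        return out, info
    return out
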