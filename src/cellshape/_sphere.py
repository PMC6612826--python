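"""Shared spherical geometry: the (theta, phi) map container, unit vectors,
and signed spherical-triangle areas with analytic derivatives.

Signed areas use the Van Oosterom & Strackee solid-angle formula
``Omega = 2 atan2(det[v1 v2 v3], 1 + v1.v2 + v2.v3 + v3.v1)``, which is
positive for counterclockwise (outward-wound) spherical triangles and flips
sign on fold-over — exactly the property the area-equalization optimizer
needs to detect inverted faces.  Its closed-form gradient with respect to
the vertex angles is implemented alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphericalMap",
    "unit_vectors",
    "triangle_signed_areas",
    "quad_signed_areas",
    "quad_area_jacobian_blocks",
]


@dataclass
class SphericalMap:
    """Per-vertex spherical coordinates of a parameterized mesh.

    ``theta``: colatitude in [0, pi] (0 at the north pole);
    ``phi``: longitude in [0, 2*pi);
    ``mesh_ref``: the SurfaceMesh these angles parameterize.
    """

    theta: np.ndarray
    phi: np.ndarray
    mesh_ref: object = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.theta.shape != self.phi.shape:
            raise ValueError("theta and phi must have the same shape")

    def unit_vectors(self) -> np.ndarray:
        return unit_vectors(self.theta, self.phi)

    def copy(self) -> "SphericalMap":
        return SphericalMap(self.theta.copy(), self.phi.copy(), self.mesh_ref)


def unit_vectors(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """(..., 3) points on the unit sphere."""
    st, ct = np.sin(theta), np.cos(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=-1)


def _angle_tangents(theta: np.ndarray, phi: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """dv/dtheta and dv/dphi for unit-sphere points, shape (..., 3)."""
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    dv_dt = np.stack([ct * cp, ct * sp, -st], axis=-1)
    dv_dp = np.stack([-st * sp, st * cp, np.zeros_like(st)], axis=-1)
    return dv_dt, dv_dp


def triangle_signed_areas(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray
                          ) -> np.ndarray:
    """Signed spherical excess of triangles given unit-vector vertices."""
    det = np.einsum("...i,...i->...", v1, np.cross(v2, v3))
    den = (1.0 + np.einsum("...i,...i->...", v1, v2)
           + np.einsum("...i,...i->...", v2, v3)
           + np.einsum("...i,...i->...", v3, v1))
    return 2.0 * np.arctan2(det, den)


def _triangle_area_vertex_grads(v1, v2, v3):
    """Gradients of the signed excess w.r.t. each vertex vector.

    Returns (g1, g2, g3), each (..., 3).
    """
    c23, c31, c12 = np.cross(v2, v3), np.cross(v3, v1), np.cross(v1, v2)
    det = np.einsum("...i,...i->...", v1, c23)
    den = (1.0 + np.einsum("...i,...i->...", v1, v2)
           + np.einsum("...i,...i->...", v2, v3)
           + np.einsum("...i,...i->...", v3, v1))
    scale = 2.0 / (det ** 2 + den ** 2)
    sN = (scale * den)[..., None]
    sD = (scale * det)[..., None]
    g1 = sN * c23 - sD * (v2 + v3)
    g2 = sN * c31 - sD * (v1 + v3)
    g3 = sN * c12 - sD * (v1 + v2)
    return g1, g2, g3


def quad_signed_areas(theta: np.ndarray, phi: np.ndarray,
                      faces: np.ndarray) -> np.ndarray:
    """Signed spherical area per face (quads split along the 0-2 diagonal;
    triangle faces handled directly)."""
    v = unit_vectors(theta, phi)[faces]  # (F, C, 3)
    a1 = triangle_signed_areas(v[:, 0], v[:, 1], v[:, 2])
    if faces.shape[1] == 3:
        return a1
    a2 = triangle_signed_areas(v[:, 0], v[:, 2], v[:, 3])
    return a1 + a2


def quad_area_jacobian_blocks(theta: np.ndarray, phi: np.ndarray,
                              faces: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Areas and their partials w.r.t. the 4 corner angles of every quad.

    Returns ``(areas, d_dtheta, d_dphi)`` with shapes (F,), (F, 4), (F, 4):
    closed-form derivatives of the signed quad area with respect to the
    theta and phi of each corner vertex.
    """
    v_all = unit_vectors(theta, phi)
    dt_all, dp_all = _angle_tangents(theta, phi)
    v = v_all[faces]            # (F, 4, 3)
    dt = dt_all[faces]
    dp = dp_all[faces]

    a1 = triangle_signed_areas(v[:, 0], v[:, 1], v[:, 2])
    a2 = triangle_signed_areas(v[:, 0], v[:, 2], v[:, 3])
    g10, g11, g12 = _triangle_area_vertex_grads(v[:, 0], v[:, 1], v[:, 2])
    g20, g22, g23 = _triangle_area_vertex_grads(v[:, 0], v[:, 2], v[:, 3])

    gv = np.zeros_like(v)       # gradient w.r.t. each corner vector
    gv[:, 0] = g10 + g20
    gv[:, 1] = g11
    gv[:, 2] = g12 + g22
    gv[:, 3] = g23

    d_dtheta = np.einsum("fci,fci->fc", gv, dt)
    d_dphi = np.einsum("fci,fci->fc", gv, dp)
    return a1 + a2, d_dtheta, d_dphi
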