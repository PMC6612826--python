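"""Fundamental 2D shape geometry.

Outlines are extracted from binary masks as ordered, evenly spaced boundary
landmarks; alignment removes translation and in-plane rotation; preshapes
additionally remove scale.  The Hausdorff distance defined here is the
evaluation metric used throughout the package, in 2D and 3D alike.

Conventions (fixed package-wide):

* image coordinates are 0-based pixel centers, ``x`` = column, ``y`` = row;
* boundary winding is counterclockwise as seen on screen (y axis pointing
  down), i.e. the shoelace sum over stored ``(x, y)`` is negative;
* tracing starts from the leftmost boundary point, ties broken by smallest y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "MaskImage2D",
    "Outline2D",
    "Preshape",
    "extract_outline",
    "align_outline",
    "to_preshape",
    "hausdorff_distance",
]

#: Default landmark counts for cell and nuclear outlines.
DEFAULT_CELL_POINTS = 2000
DEFAULT_NUCLEUS_POINTS = 1000


@dataclass
class MaskImage2D:
    """A single-cell binary mask.

    Parameters
    ----------
    pixels
        2D boolean array, row-major; True marks foreground.
    pixel_size
        Physical size of one pixel.  Everything downstream works in pixel
        units, so this is metadata only.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("MaskImage2D expects a 2D array")


@dataclass
class Outline2D:
    """Ordered, evenly spaced boundary landmarks of one 2D shape.

    ``points`` is an (n, 2) array of (x, y) coordinates in pixels.  The
    outline is closed implicitly: the last point precedes the first.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("Outline2D expects an (n, 2) array")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class Preshape:
    """A shape with location and scale removed.

    The removed centroid and Frobenius norm are kept so the original
    coordinates can be restored exactly; they are the explicit
    normalization parameters counted toward a model's total dimension.
    """

    points: np.ndarray
    scale: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def restore(self) -> Outline2D:
        """Undo the normalization: returns the original outline."""
        return Outline2D(self.points * self.scale + self.center)


def _boundary_polygon(mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel boundary polygon of a single-component mask.

    Marching squares at level 0.5; returns (m, 2) array of (x, y) vertices
    with the first vertex not repeated at the end.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary at level 0.5")
    # outer boundary = longest contour (single component, holes excluded)
    contour = max(contours, key=lambda c: c.shape[0])
    poly = contour[:, ::-1]  # (row, col) -> (x, y)
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    # enforce counterclockwise on screen (negative shoelace with y down)
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 > 0:
        poly = poly[::-1]
    return poly


def _validate_mask(mask: MaskImage2D) -> np.ndarray:
    pixels = mask.pixels
    if not pixels.any():
        raise ValueError("empty mask: no foreground pixels")
    labels, n_comp = measure.label(pixels, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")
    if int(pixels.sum()) < 4:
        raise ValueError("mask has fewer than 4 foreground pixels")
    return pixels


def extract_outline(mask: MaskImage2D, n_points: int) -> Outline2D:
    """Trace ``n_points`` evenly spaced landmarks along the mask boundary.

    Landmarks are equally spaced in arc length along the sub-pixel boundary
    polygon, starting from the leftmost boundary vertex (ties: smallest y),
    with counterclockwise-on-screen winding.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pixels = _validate_mask(mask)
    poly = _boundary_polygon(pixels)

    # anchor at the leftmost vertex, smallest y on ties
    order = np.lexsort((poly[:, 1], poly[:, 0]))
    poly = np.roll(poly, -order[0], axis=0)

    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = arc[-1]
    if perimeter == 0:
        raise ValueError("degenerate boundary with zero perimeter")
    targets = np.arange(n_points) * perimeter / n_points
    x = np.interp(targets, arc, closed[:, 0])
    y = np.interp(targets, arc, closed[:, 1])
    return Outline2D(np.column_stack([x, y]))


def align_outline(outline: Outline2D, *, isotropy_tol: float = 1e-12) -> Outline2D:
    """Centre an outline and rotate its major axis onto +x.

    The second-moment major axis is rotated onto the x axis; the remaining
    180-degree ambiguity is resolved by requiring non-negative x-skewness
    (third central moment of the x coordinates), mirroring the convention
    used for 3D descriptor alignment.  Landmark ordering is re-anchored at
    the leftmost point after rotation.  Nearly isotropic outlines (no
    preferred axis within ``isotropy_tol`` of the moment magnitude) are only
    centered, which makes alignment idempotent.
    """
    pts = outline.points - outline.points.mean(axis=0)
    if np.allclose(pts, 0):
        raise ValueError("degenerate outline: all points identical")
    mu20 = np.mean(pts[:, 0] ** 2)
    mu02 = np.mean(pts[:, 1] ** 2)
    mu11 = np.mean(pts[:, 0] * pts[:, 1])
    b, a = 2 * mu11, mu20 - mu02
    if np.hypot(a, b) > isotropy_tol * (mu20 + mu02):
        angle = 0.5 * np.arctan2(b, a)
        c, s = np.cos(-angle), np.sin(-angle)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    if np.mean(pts[:, 0] ** 3) < 0:
        pts = -pts  # 180-degree rotation about the centroid
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = np.roll(pts, -order[0], axis=0)
    return Outline2D(pts)


def to_preshape(outline: Outline2D) -> Preshape:
    """Remove location (centroid) and scale (Frobenius norm) from an outline."""
    center = outline.points.mean(axis=0)
    centered = outline.points - center
    scale = float(np.linalg.norm(centered))
    if scale == 0:
        raise ValueError("zero-norm outline cannot be normalized to a preshape")
    return Preshape(points=centered / scale, scale=scale, center=center)


def hausdorff_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets.

    ``max`` over both directions of the maximal nearest-neighbour Euclidean
    distance — the worst match between the two sets.  Exact (KD-tree
    nearest-neighbour queries), works for 2D and 3D point sets.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("hausdorff_distance requires nonempty point sets")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    d_ab = cKDTree(B).query(A, k=1)[0].max()
    d_ba = cKDTree(A).query(B, k=1)[0].max()
    return float(max(d_ab, d_ba))
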