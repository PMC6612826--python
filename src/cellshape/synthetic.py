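"""Seeded generators for synthetic cell shapes.

Two families drive the test battery and examples:

* smooth, roundish cells/nuclei (Fourier-perturbed disks in 2D, spherical-
  harmonic-perturbed ellipsoids in 3D), standing in for typical adherent
  cells;
* neuron-like cells ("SNL"): a soma with a small number of long, thin,
  curved neurites — deliberately hard cases for spherical parameterization.

3D SNL volumes extrude a central 2D slice: slices above and below carry a
scaled-down copy of the soma (semicircular taper), and neurites appear only
in the central third of the occupied slices, as thin structures in
substrate-attached cells are quasi-2D.  Default extent is 256 x 256 x 24
voxels.

Every generator is deterministic given its seed; batches derive one RNG
stream per shape from (master seed, shape index), so they are reproducible
and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .mesh_surface import VoxelVolume
from .shape_core import MaskImage2D

__all__ = [
    "SNLParams",
    "PairParams",
    "generate_snl_2d",
    "generate_snl_3d",
    "generate_blob_3d",
    "generate_cell_nucleus_pair_2d",
    "shape_rng",
]


def shape_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one shape in a batch."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


@dataclass
class SNLParams:
    """Parameters of the neuron-like cell generator.

    ``n_neurites`` is either a fixed count or an inclusive (lo, hi) range
    sampled per cell.  ``boundary_roughness`` is the total relative
    amplitude of the random-phase Fourier perturbation of the soma
    boundary.  All lengths are in pixels.
    """

    soma_radius_range: tuple[float, float] = (20.0, 40.0)
    n_neurites: int | tuple[int, int] = 2
    neurite_length_range: tuple[float, float] = (60.0, 150.0)
    neurite_width_range: tuple[float, float] = (3.0, 7.0)
    boundary_roughness: float = 0.08
    image_size: tuple[int, int] = (256, 256)
    n_slices: int = 24
    thickness: int = 16
    seed: int = 0


def _fourier_radius(rng: np.random.Generator, base: float, roughness: float,
                    angles: np.ndarray) -> np.ndarray:
    """Radial profile of a disk perturbed by 5 random-phase Fourier modes."""
    orders = rng.choice(np.arange(2, 9), size=5, replace=False)
    amps = rng.uniform(0.2, 1.0, size=5)
    amps = roughness * amps / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, size=5)
    rho = np.ones_like(angles)
    for k, a, p in zip(orders, amps, phases):
        rho += a * np.cos(k * angles + p)
    return base * rho


def _fill_polygon(rr_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.polygon(rr_xy[:, 1], rr_xy[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def _soma_mask(rng: np.random.Generator, params: SNLParams
               ) -> tuple[np.ndarray, float, np.ndarray]:
    ny, nx = params.image_size
    center = np.array([nx / 2.0, ny / 2.0])
    radius = rng.uniform(*params.soma_radius_range)
    angles = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    rho = _fourier_radius(rng, radius, params.boundary_roughness, angles)
    poly = center + np.column_stack(
        [rho * np.cos(angles), rho * np.sin(angles)])
    return _fill_polygon(poly, (ny, nx)), radius, center


def _neurite_mask(rng: np.random.Generator, params: SNLParams,
                  center: np.ndarray, radius: float,
                  n_neurites: int) -> np.ndarray:
    """Curved thick strokes attached at soma boundary angles >= 60 deg apart."""
    ny, nx = params.image_size
    mask = np.zeros((ny, nx), dtype=bool)
    angles: list[float] = []
    for _ in range(200):
        if len(angles) == n_neurites:
            break
        a = rng.uniform(0, 2 * np.pi)
        if all(min(abs(a - b), 2 * np.pi - abs(a - b)) >= np.pi / 3
               for b in angles):
            angles.append(a)
    if len(angles) < n_neurites:
        raise RuntimeError("neurite placement failed after retries")
    for a in angles:
        length = rng.uniform(*params.neurite_length_range)
        width = rng.uniform(*params.neurite_width_range)
        bend = rng.uniform(-0.6, 0.6)
        d0 = np.array([np.cos(a), np.sin(a)])
        d2 = np.array([np.cos(a + bend), np.sin(a + bend)])
        p0 = center + (radius * 0.8) * d0
        p2 = p0 + length * d2
        perp = np.array([-d0[1], d0[0]])
        p1 = p0 + 0.5 * length * d0 + rng.uniform(-0.3, 0.3) * length * perp
        t = np.linspace(0, 1, max(32, int(2 * length)))[:, None]
        curve = ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2)
        for cx, cy in curve:
            rr, cc = draw.disk((cy, cx), max(width / 2.0, 1.0),
                               shape=(ny, nx))
            mask[rr, cc] = True
    return mask


def _snl_components(params: SNLParams
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    rng = np.random.default_rng(params.seed)
    soma, radius, center = _soma_mask(rng, params)
    if isinstance(params.n_neurites, tuple):
        lo, hi = params.n_neurites
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(params.n_neurites)
    neurites = (_neurite_mask(rng, params, center, radius, n)
                if n > 0 else np.zeros_like(soma))
    return soma, neurites, n


def _clean_2d(mask: np.ndarray) -> np.ndarray:
    """Largest component, holes filled."""
    labels, ncomp = ndimage.label(mask)
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   range(1, ncomp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def generate_snl_2d(params: SNLParams) -> MaskImage2D:
    """One neuron-like 2D cell mask: perturbed-disk soma plus curved
    thick neurite strokes, single connected component, deterministic."""
    soma, neurites, _ = _snl_components(params)
    return MaskImage2D(_clean_2d(soma | neurites))


def _scale_mask(mask: np.ndarray, factor: float,
                center: np.ndarray) -> np.ndarray:
    """Scale a 2D mask about ``center`` (y, x order) by ``factor``."""
    if factor >= 0.999:
        return mask.copy()
    inv = 1.0 / factor
    offset = center * (1.0 - inv)
    out = ndimage.affine_transform(
        mask.astype(np.uint8), np.array([inv, inv]), offset=offset,
        order=0, output_shape=mask.shape, mode="constant", cval=0)
    return out.astype(bool)


def generate_snl_3d(params: SNLParams) -> VoxelVolume:
    """Extruded neuron-like 3D cell in a (x, y, z) voxel grid.

    The central slice is exactly the 2D generator's output for the same
    seed.  Going up or down, the soma shrinks with a semicircular profile
    across the occupied ``thickness`` slices (clamped to a minimal disk so
    the stack never pinches off); neurites exist only in the central third
    of the occupied slices.
    """
    if params.n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    soma, neurites, _ = _snl_components(params)
    central = _clean_2d(soma | neurites)
    ny, nx = params.image_size
    nz = params.n_slices
    zc = nz // 2
    half = params.thickness / 2.0
    com = np.array(ndimage.center_of_mass(soma))  # (y, x)

    slices = np.zeros((nz, ny, nx), dtype=bool)
    for z in range(nz):
        dz = z - zc
        if abs(dz) > half:
            continue
        if dz == 0:
            slices[z] = central
            continue
        s = np.sqrt(max(1.0 - (dz / half) ** 2, 0.0))
        s = max(s, 0.2)
        sl = _scale_mask(soma, s, com)
        if not sl.any():
            rr, cc = draw.disk((com[0], com[1]), 2.0, shape=(ny, nx))
            sl = np.zeros((ny, nx), dtype=bool)
            sl[rr, cc] = True
        if abs(dz) <= params.thickness / 6.0:
            sl = sl | neurites
        slices[z] = _clean_2d(sl)
    # axes (x, y, z)
    return VoxelVolume(np.transpose(slices, (2, 1, 0)))


def generate_blob_3d(size: float = 24.0, elongation: float = 1.4,
                     roughness: float = 0.1, seed: int = 0,
                     z_ratio: float = 0.4) -> VoxelVolume:
    """Smooth HeLa-like blob: a voxelized ellipsoid with a low-order
    spherical-harmonic radial perturbation; genus-0 by construction.

    ``size`` is the semi-axis along x; the y semi-axis is ``size /
    elongation`` and the z semi-axis ``z_ratio * size`` (adherent cells
    are flat).
    """
    import scipy.special as special

    rng = np.random.default_rng(seed)
    a, b, c = size, size / elongation, z_ratio * size
    margin = 3
    nx = int(2 * (a + margin)) + 1
    ny = int(2 * (b + margin)) + 1
    nz = int(2 * (c + margin)) + 1
    x, y, z = np.meshgrid(
        np.arange(nx) - nx // 2,
        np.arange(ny) - ny // 2,
        np.arange(nz) - nz // 2, indexing="ij")
    u = np.stack([x / a, y / b, z / c])
    r = np.sqrt((u ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, u[2] / r, 1.0), -1, 1))
    phi = np.mod(np.arctan2(u[1], u[0]), 2 * np.pi)
    rho = np.ones_like(r)
    if roughness > 0:
        for l in range(2, 4):
            for m in range(0, l + 1):
                amp = roughness * rng.normal() / (2 * l + 1)
                y_lm = special.sph_harm_y(l, m, theta, phi)
                rho += amp * np.sqrt(4 * np.pi) * y_lm.real
    vox = r <= rho
    vox = ndimage.binary_fill_holes(vox)
    labels, ncomp = ndimage.label(vox)
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   range(1, ncomp + 1))
        vox = labels == (1 + int(np.argmax(sizes)))
    return VoxelVolume(vox)


@dataclass
class PairParams:
    """Parameters of the paired cell + nucleus 2D generator."""

    cell_radius_range: tuple[float, float] = (60.0, 90.0)
    nucleus_radius_range: tuple[float, float] = (22.0, 34.0)
    offset_mean: tuple[float, float] = (8.0, 0.0)
    offset_std: tuple[float, float] = (4.0, 4.0)
    cell_roughness: float = 0.08
    nucleus_roughness: float = 0.05
    cell_elongation_range: tuple[float, float] = (1.0, 1.6)
    image_size: tuple[int, int] = (256, 256)


def generate_cell_nucleus_pair_2d(params: PairParams, seed: int
                                  ) -> tuple[MaskImage2D, MaskImage2D]:
    """A cell mask and a nucleus mask strictly inside it.

    The nucleus center offset from the cell center is drawn from a normal
    distribution with the configured mean and spread; placement is retried
    (re-drawing the offset) until the nucleus lies strictly inside the
    cell.
    """
    rng = np.random.default_rng(seed)
    ny, nx = params.image_size
    center = np.array([nx / 2.0, ny / 2.0])
    angles = np.linspace(0, 2 * np.pi, 720, endpoint=False)

    elong = rng.uniform(*params.cell_elongation_range)
    cell_r = rng.uniform(*params.cell_radius_range)
    tilt = rng.uniform(0, np.pi)
    rho_c = _fourier_radius(rng, cell_r, params.cell_roughness, angles)
    stretch = 1.0 / np.sqrt(
        np.cos(angles - tilt) ** 2 * elong ** 2 + np.sin(angles - tilt) ** 2)
    poly_c = center + np.column_stack(
        [rho_c * stretch * elong * np.cos(angles),
         rho_c * stretch * elong * np.sin(angles)]) / elong
    cell = ndimage.binary_fill_holes(
        _fill_polygon(poly_c, (ny, nx)))
    interior = ndimage.binary_erosion(cell, iterations=2)

    nuc_r = rng.uniform(*params.nucleus_radius_range)
    rho_n = _fourier_radius(rng, nuc_r, params.nucleus_roughness, angles)
    for _ in range(100):
        offset = rng.normal(params.offset_mean, params.offset_std)
        poly_n = center + offset + np.column_stack(
            [rho_n * np.cos(angles), rho_n * np.sin(angles)])
        nucleus = _fill_polygon(poly_n, (ny, nx))
        if nucleus.any() and not (nucleus & ~interior).any():
            return MaskImage2D(cell), MaskImage2D(nucleus)
    raise RuntimeError("nucleus containment failed after retries")
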