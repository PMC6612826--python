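"""Reconstruction-error metrics and the evolution-energy benchmark.

Reconstruction quality is the mean Hausdorff distance over a dataset: in
2D between outline landmark sets, in 3D between mesh vertex sets.  The
pixel-level error (non-overlap area over original area) is a secondary
mask-based metric.  Joint cell+nucleus models are scored by averaging the
mean cell error and the mean nuclear error, weighting both equally so
cell-shape errors do not drown out the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_surface import SurfaceMesh, VoxelVolume, voxels_to_quad_mesh
from .shape_core import (MaskImage2D, Outline2D, extract_outline,
                         hausdorff_distance)
from .shape_space import evolution_energy

__all__ = [
    "ErrorReport",
    "EnergyBenchmarkResult",
    "reconstruction_error_2d",
    "reconstruction_error_3d",
    "pixel_level_error",
    "joint_error",
    "energy_benchmark",
]


@dataclass
class ErrorReport:
    """Per-shape and mean reconstruction errors with model metadata."""

    per_shape_errors: np.ndarray
    method: str = ""
    latent_dims: int = 0
    n_norm_params: int = 0
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.per_shape_errors = np.asarray(self.per_shape_errors, dtype=float)

    @property
    def mean_error(self) -> float:
        return float(self.per_shape_errors.mean())


def _as_outline_points(shape, n_points: int) -> np.ndarray:
    if isinstance(shape, Outline2D):
        return shape.points
    if isinstance(shape, MaskImage2D):
        return extract_outline(shape, n_points).points
    return np.asarray(shape, dtype=float)


def reconstruction_error_2d(original, reconstructed,
                            n_points: int = 2000) -> float:
    """Hausdorff distance between outline landmark sets.

    Masks are converted to outlines first; outlines are used as-is.
    """
    a = _as_outline_points(original, n_points)
    b = _as_outline_points(reconstructed, n_points)
    if b.size == 0:
        raise ValueError("empty reconstruction")
    return hausdorff_distance(a, b)


def reconstruction_error_3d(original, reconstructed: SurfaceMesh) -> float:
    """Hausdorff distance between mesh vertex sets.

    ``original`` may be a voxel volume (converted to its boundary mesh) or
    a mesh.  Vertex point sets are compared, matching the landmark-based
    2D treatment.
    """
    if isinstance(original, VoxelVolume):
        original = voxels_to_quad_mesh(original)
    return hausdorff_distance(original.vertices, reconstructed.vertices)


def pixel_level_error(original: MaskImage2D,
                      reconstructed: MaskImage2D) -> float:
    """Non-overlap area over original area: |A xor B| / |A|."""
    a, b = original.pixels, reconstructed.pixels
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n_orig = int(a.sum())
    if n_orig == 0:
        raise ValueError("empty original mask")
    return float(np.logical_xor(a, b).sum() / n_orig)


def joint_error(cell_errors, nuclear_errors) -> float:
    """Equal-weight average of the mean cell and mean nuclear errors."""
    cell_errors = np.asarray(cell_errors, dtype=float)
    nuclear_errors = np.asarray(nuclear_errors, dtype=float)
    if cell_errors.size == 0 or nuclear_errors.size == 0:
        raise ValueError("error lists must be nonempty")
    return float((cell_errors.mean() + nuclear_errors.mean()) / 2.0)


@dataclass
class EnergyBenchmarkResult:
    """Normalized evolution energies over randomly sampled shape pairs."""

    energies: np.ndarray
    pairs: np.ndarray
    n_skipped_degenerate: int = 0

    @property
    def mean(self) -> float:
        return float(self.energies.mean())

    @property
    def minimum(self) -> float:
        return float(self.energies.min())


def energy_benchmark(model, latents: np.ndarray, n_pairs: int,
                     N_steps: int = 10, seed: int = 0,
                     eps: float = 1e-6) -> EnergyBenchmarkResult:
    """Normalized evolution energy over seeded random pairs of shapes.

    ``latents`` is the (n, k) matrix of embedded dataset shapes.  Distinct
    index pairs are sampled without replacement; pairs whose endpoint
    shapes are degenerate (Hausdorff distance <= eps) are skipped and
    counted.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    n = latents.shape[0]
    if n < 2 or n_pairs < 1:
        raise ValueError("need >= 2 embedded shapes and n_pairs >= 1")
    rng = np.random.default_rng(seed)
    total = n * (n - 1) // 2
    n_pairs = min(n_pairs, total)
    chosen = rng.choice(total, size=n_pairs, replace=False)
    # unrank the flat upper-triangle index
    ii, jj = np.triu_indices(n, k=1)
    pairs = np.stack([ii[chosen], jj[chosen]], axis=1)

    energies, kept = [], []
    skipped = 0
    for i, j in pairs:
        try:
            res = evolution_energy(model, latents[i], latents[j],
                                   N=N_steps, eps=eps)
        except ValueError:
            skipped += 1
            continue
        energies.append(res.normalized_energy)
        kept.append((i, j))
    if not energies:
        raise ValueError("all sampled pairs were degenerate")
    return EnergyBenchmarkResult(energies=np.array(energies),
                                 pairs=np.array(kept),
                                 n_skipped_degenerate=skipped)
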