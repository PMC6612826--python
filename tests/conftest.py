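"""Shared fixtures: small geometric masks/volumes and pipeline products.

Everything is generated programmatically and seeded; session scope keeps
the expensive 3D parameterizations shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import cellshape as cs


@pytest.fixture(scope="session")
def square_mask() -> cs.MaskImage2D:
    m = np.zeros((12, 12), bool)
    m[1:11, 1:11] = True
    return cs.MaskImage2D(m)


@pytest.fixture(scope="session")
def disk_mask() -> cs.MaskImage2D:
    yy, xx = np.mgrid[:64, :64]
    return cs.MaskImage2D((xx - 32) ** 2 + (yy - 32) ** 2 <= 20 ** 2)


@pytest.fixture(scope="session")
def snl_outlines() -> list[cs.Outline2D]:
    """Aligned outlines of 10 small neuron-like cells (64 landmarks)."""
    masks = [cs.generate_snl_2d(cs.SNLParams(seed=s)) for s in range(10)]
    return [cs.align_outline(cs.extract_outline(m, 64)) for m in masks]


@pytest.fixture(scope="session")
def tiny_outlines() -> list[cs.Outline2D]:
    """10 aligned 16-landmark outlines for dense linear-algebra oracles."""
    masks = [cs.generate_snl_2d(cs.SNLParams(seed=100 + s))
             for s in range(10)]
    return [cs.align_outline(cs.extract_outline(m, 16)) for m in masks]


@pytest.fixture(scope="session")
def voxel_sphere() -> cs.VoxelVolume:
    xx, yy, zz = np.mgrid[:20, :20, :20]
    return cs.VoxelVolume(
        (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 <= 64)


@pytest.fixture(scope="session")
def voxel_rod() -> cs.VoxelVolume:
    rod = np.zeros((14, 3, 3), bool)
    rod[1:13, :, :] = True
    return cs.VoxelVolume(rod)


@pytest.fixture(scope="session")
def sphere_pipeline(voxel_sphere):
    """(mesh, spherical map) of the voxel sphere after area equalization."""
    mesh = cs.voxels_to_quad_mesh(voxel_sphere)
    init = cs.initial_parameterization(mesh, cs.graph_diameter_poles(mesh))
    mapping, diag = cs.optimize_parameterization(mesh, init)
    return mesh, mapping, diag


@pytest.fixture(scope="session")
def blob_pipeline():
    """Rough ellipsoid blob through the robust pipeline."""
    vol = cs.generate_blob_3d(size=20, roughness=0.15, seed=7)
    mesh, mapping, diag = cs.parameterize_robust(
        vol, cs.RPDMOptions(working_order=15))
    return vol, mesh, mapping, diag


def brute_force_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """O(|A||B|) double-loop oracle for the Hausdorff distance."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())
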