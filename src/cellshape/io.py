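"""Readers and writers for the package's on-disk formats.

Masks and volumes travel as TIFF (multi-page for volumes, page = z slice)
or PNG; outlines as two-column delimited text; meshes as OBJ/PLY through
trimesh; spherical maps as per-vertex (theta, phi) tables; descriptors as
(l, m, Re, Im) tables per coordinate; PCA models as HDF5 containers.
"""

from __future__ import annotations

import numpy as np

from .mesh_surface import SurfaceMesh, VoxelVolume
from .shape_core import MaskImage2D, Outline2D

__all__ = [
    "read_mask_2d",
    "write_mask_2d",
    "read_volume",
    "write_volume",
    "save_outline",
    "load_outline",
    "export_mesh",
    "save_spherical_map",
    "load_spherical_map",
    "save_descriptor",
    "load_descriptor",
    "save_pca_model",
    "load_pca_model",
]


def read_mask_2d(path) -> MaskImage2D:
    """Load a binary 2D mask from single-page TIFF or PNG."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return MaskImage2D(arr > 0)


def write_mask_2d(path, mask: MaskImage2D) -> None:
    path = str(path)
    arr = mask.pixels.astype(np.uint8) * 255
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, arr)


def read_volume(path) -> VoxelVolume:
    """Multi-page TIFF (pages = z slices, each page (y, x)) -> (x, y, z)."""
    import tifffile
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return VoxelVolume(np.transpose(stack > 0, (2, 1, 0)))


def write_volume(path, volume: VoxelVolume) -> None:
    import tifffile
    stack = np.transpose(volume.voxels, (2, 1, 0)).astype(np.uint8) * 255
    tifffile.imwrite(str(path), stack)


def save_outline(path, outline: Outline2D) -> None:
    np.savetxt(str(path), outline.points,
               header=f"n_points={outline.n_points} columns=x,y")


def load_outline(path) -> Outline2D:
    return Outline2D(np.loadtxt(str(path)))


def export_mesh(path, mesh: SurfaceMesh) -> None:
    """Triangulated OBJ or PLY export."""
    import trimesh
    tm = trimesh.Trimesh(vertices=mesh.vertices,
                         faces=mesh.triangulated(), process=False)
    tm.export(str(path))


def save_spherical_map(path, mapping) -> None:
    np.savetxt(str(path), np.column_stack([mapping.theta, mapping.phi]),
               header="columns=theta,phi")


def load_spherical_map(path):
    from ._sphere import SphericalMap
    data = np.loadtxt(str(path))
    return SphericalMap(theta=data[:, 0], phi=data[:, 1])


def save_descriptor(path, desc) -> None:
    """Delimited text: l, m, then Re/Im per coordinate."""
    from .spharm import coeff_index
    rows = []
    for l in range(desc.max_order + 1):
        for m in range(-l, l + 1):
            c = desc.coefficients[:, coeff_index(l, m)]
            rows.append([l, m] + [v for z in c for v in (z.real, z.imag)])
    np.savetxt(str(path), np.array(rows),
               header=f"max_order={desc.max_order} d={desc.d} "
                      "columns=l,m,(re,im per coordinate)")


def load_descriptor(path):
    from .spharm import SPHARMDescriptor, coeff_index
    data = np.loadtxt(str(path))
    L = int(round(np.sqrt(data.shape[0]) - 1))
    d = (data.shape[1] - 2) // 2
    coeffs = np.zeros((d, (L + 1) ** 2), dtype=complex)
    for row in data:
        l, m = int(row[0]), int(row[1])
        coeffs[:, coeff_index(l, m)] = row[2::2] + 1j * row[3::2]
    return SPHARMDescriptor(coefficients=coeffs, max_order=L)


def save_pca_model(path, model) -> None:
    """HDF5 container: datasets mean/components/explained_variance plus
    layout metadata attributes."""
    import h5py
    with h5py.File(str(path), "w") as f:
        f.create_dataset("mean", data=model.mean)
        f.create_dataset("components", data=model.components)
        f.create_dataset("explained_variance", data=model.explained_variance)
        f.attrs["k"] = model.k
        f.attrs["d"] = model.d
        f.attrs["n_norm_params"] = model.n_norm_params
        if hasattr(model, "n_points"):
            f.attrs["kind"] = "outline_pca"
            f.attrs["n_points"] = model.n_points
        else:
            f.attrs["kind"] = "descriptor_pca"
            f.attrs["max_order"] = model.max_order


def load_pca_model(path):
    import h5py
    from .outline_models import OutlinePCAModel
    from .shape_space import ShapeSpaceModel
    with h5py.File(str(path), "r") as f:
        common = dict(
            mean=f["mean"][()], components=f["components"][()],
            explained_variance=f["explained_variance"][()],
            d=int(f.attrs["d"]),
            n_norm_params=int(f.attrs["n_norm_params"]))
        if f.attrs["kind"] == "outline_pca":
            return OutlinePCAModel(n_points=int(f.attrs["n_points"]), **common)
        return ShapeSpaceModel(max_order=int(f.attrs["max_order"]), **common)
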