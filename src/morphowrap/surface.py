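"""Surface extraction from confocal intensity volumes (the *extract* stage).

A scanned specimen arrives as a stack of grayscale slices with anisotropic
voxel spacing (finer in-plane than between slices).  The stage smooths the
intensities with a Gaussian filter, resamples the lattice to an isotropic
cube size, triangulates the iso-surface at a user-chosen intensity
threshold with marching cubes, and optionally relaxes the resulting mesh
with a few passes of uniform Laplacian smoothing.

All coordinates are micrometres.  World axes are ``(x, y, z)`` where ``z``
is the stack (depth / lateral) axis, i.e. the reverse of the ``(nz, ny,
nx)`` array axis order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from skimage import measure

__all__ = [
    "IntensityVolume",
    "TriangleMesh",
    "gaussian_blur",
    "extract_surface",
    "smooth_mesh",
]

#: Laplacian smoothing beyond this many passes visibly shrinks the mesh.
RECOMMENDED_MAX_SMOOTHING_PASSES = 3


@dataclass
class IntensityVolume:
    """A 3D scalar lattice with voxel spacing in micrometres.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities, slice-major (stack axis first).
    spacing : tuple of float
        Voxel edge lengths ``(dz, dy, dx)`` in µm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D lattice, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) of the lattice in µm (node-to-node)."""
        return tuple((n - 1) * s for n, s in zip(self.voxels.shape, self.spacing))


@dataclass
class TriangleMesh:
    """Triangulated surface: vertices in µm plus triangular faces.

    Faces index into ``vertices``; a face must not repeat a vertex.
    """

    vertices: np.ndarray  # (n, 3) float, µm, world (x, y, z)
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValueError("faces must have shape (m, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("a face repeats a vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Total surface area in µm²."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def gaussian_blur(vol: IntensityVolume, sigma_um: float) -> IntensityVolume:
    """Gaussian-smooth a volume with an isotropic physical bandwidth.

    ``sigma_um`` is converted per axis into voxel units through the voxel
    spacing, so the blur is isotropic in µm even on anisotropic lattices.
    Boundaries are handled by reflection, which keeps the specimen bright
    at stack edges and conserves total intensity.

    A ``sigma_um`` of zero returns the input unchanged.
    """
    sigma_um = float(sigma_um)
    if sigma_um < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_um}")
    if sigma_um == 0.0:
        return vol
    sigma_vox = [sigma_um / s for s in vol.spacing]
    smoothed = ndimage.gaussian_filter(vol.voxels.astype(float), sigma=sigma_vox, mode="reflect")
    return IntensityVolume(smoothed, vol.spacing)


def _resample_isotropic(vol: IntensityVolume, cube_size_um: float) -> np.ndarray:
    """Trilinearly resample onto an isotropic lattice of pitch ``cube_size_um``.

    Node ``i`` of the output along an axis sits at physical position
    ``i * cube_size_um`` from the volume corner, so marching-cubes vertex
    coordinates times the cube size are already µm in volume coordinates.
    """
    coords = []
    for n, s in zip(vol.voxels.shape, vol.spacing):
        extent = (n - 1) * s
        n_new = max(int(np.floor(extent / cube_size_um)) + 1, 2)
        coords.append(np.arange(n_new) * (cube_size_um / s))
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        vol.voxels.astype(float), np.stack(grid), order=1, mode="nearest"
    )


def extract_surface(vol: IntensityVolume, threshold: float, cube_size_um: float) -> TriangleMesh:
    """Marching-cubes iso-surface at ``threshold`` on an isotropic lattice.

    The volume is first resampled (trilinear) to a cubic lattice with edge
    ``cube_size_um``; the standard lookup-table marching-cubes algorithm
    with linear edge interpolation then extracts the surface.  Vertices
    are returned in µm in world order ``(x, y, z)`` with ``z`` the stack
    axis, origin at the volume corner.

    Raises ``ValueError("empty surface")`` when no voxel exceeds the
    threshold; warns when the threshold lies outside the data range.
    """
    threshold = float(threshold)
    cube_size_um = float(cube_size_um)
    if cube_size_um < max(vol.spacing):
        raise ValueError(
            f"cube size {cube_size_um} µm must be at least the coarsest voxel "
            f"spacing {max(vol.spacing)} µm"
        )
    vmin, vmax = float(vol.voxels.min()), float(vol.voxels.max())
    if threshold < vmin or threshold > vmax:
        warnings.warn(
            f"threshold {threshold} outside intensity range [{vmin}, {vmax}]",
            stacklevel=2,
        )
    resampled = _resample_isotropic(vol, cube_size_um)
    if resampled.max() <= threshold:
        raise ValueError("empty surface: no voxel above threshold")
    if resampled.min() >= threshold:
        raise ValueError("empty surface: no iso-crossing below threshold")
    verts, faces, _, _ = measure.marching_cubes(resampled, level=threshold)
    verts_um = verts[:, ::-1] * cube_size_um  # (z,y,x) lattice -> (x,y,z) world µm
    return TriangleMesh(verts_um, faces)


def _vertex_adjacency(mesh: TriangleMesh) -> sparse.csr_matrix:
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(len(rows), dtype=float)
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    adj.data[:] = 1.0  # collapse duplicate edge entries
    adj.sum_duplicates()
    adj.data[:] = 1.0
    return adj


def smooth_mesh(mesh: TriangleMesh, passes: int) -> TriangleMesh:
    """Uniform Laplacian smoothing: each pass moves every vertex to the
    unweighted average of its 1-ring neighbours.

    Topology (faces, connectivity) is unchanged; ``passes == 0`` is the
    identity.  More than three passes noticeably shrinks the mesh and
    triggers a warning.  Isolated vertices (no incident face) are left in
    place with a warning.
    """
    passes = int(passes)
    if passes < 0:
        raise ValueError("passes must be a non-negative integer")
    if passes == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())
    if passes > RECOMMENDED_MAX_SMOOTHING_PASSES:
        warnings.warn(
            f"{passes} smoothing passes exceeds recommended "
            f"{RECOMMENDED_MAX_SMOOTHING_PASSES} passes; expect mesh shrinkage",
            stacklevel=2,
        )
    adj = _vertex_adjacency(mesh)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    isolated = degree == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated vertices left in place", stacklevel=2
        )
    safe_degree = np.where(isolated, 1.0, degree)
    verts = mesh.vertices.copy()
    for _ in range(passes):
        averaged = adj.dot(verts) / safe_degree[:, None]
        verts = np.where(isolated[:, None], verts, averaged)
    return TriangleMesh(verts, mesh.faces.copy())
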