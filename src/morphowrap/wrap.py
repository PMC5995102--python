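"""Grid construction, landmark warping and shrink-wrap projection (the *wrap* stage).

Point-wise comparability between specimens is established by a 2D grid of
explicitly numbered points.  The same template grid is adjusted to every
specimen — either through a thin-plate-spline warp driven by landmark
pairs, or through a coarse deformation cage bound to the grid by
mean-value coordinates — and then projected onto the specimen's surface
mesh by parallel projection along the z axis.  The projected grid is the
specimen's *cast*: point id ``i`` samples the homologous surface location
on every specimen.  Grid points whose projection ray misses the mesh are
flagged invalid and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import RBFInterpolator
from shapely.geometry import Polygon

from .surface import TriangleMesh

__all__ = [
    "GridTemplate",
    "LandmarkPairSet",
    "DeformCage",
    "Cast",
    "build_grid",
    "tps_warp",
    "cage_bind",
    "cage_deform",
    "shrink_wrap",
    "wrap_specimen",
]


@dataclass
class GridTemplate:
    """An ordered 2D point lattice.  Ids run 0..n_rows*n_cols-1 row-major:
    ``id = row * n_cols + col``.  The (u, v) plane maps to world (x, y)."""

    n_rows: int
    n_cols: int
    points: np.ndarray  # (n_rows * n_cols, 2) float µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.points.shape != (self.n_rows * self.n_cols, 2):
            raise ValueError(
                f"expected {self.n_rows * self.n_cols} 2D points, got {self.points.shape}"
            )

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols

    def row_col(self, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(ids)
        return ids // self.n_cols, ids % self.n_cols

    def with_points(self, points: np.ndarray) -> "GridTemplate":
        return GridTemplate(self.n_rows, self.n_cols, points)


@dataclass
class LandmarkPairSet:
    """Corresponding 2D landmark positions on the template and on a specimen.

    At least three non-collinear template landmarks are required so the
    warp is determined up to (at least) an affine map.
    """

    source: np.ndarray  # (k, 2) template positions, µm
    target: np.ndarray  # (k, 2) specimen positions, µm
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.source.ndim != 2 or self.source.shape[1] != 2:
            raise ValueError("source landmarks must have shape (k, 2)")
        if self.source.shape != self.target.shape:
            raise ValueError("source and target landmark counts differ")
        if len(self.source) < 3:
            raise ValueError("need at least 3 landmark pairs")
        centered = self.source - self.source.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise ValueError("template landmarks are collinear")

    def __len__(self) -> int:
        return len(self.source)


@dataclass
class DeformCage:
    """A grid elastically bound to a closed control polygon.

    ``weights[i, j]`` is the mean-value coordinate of grid point ``i``
    with respect to cage vertex ``j``; rows sum to one, and for a convex
    cage all weights are non-negative.  Moving cage vertices moves every
    grid point through the fixed weight matrix.
    """

    grid: GridTemplate
    cage: np.ndarray  # (V, 2) closed polygon vertices (not repeated)
    weights: np.ndarray  # (n_points, V)

    def __post_init__(self) -> None:
        self.cage = np.asarray(self.cage, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.n_points, len(self.cage)):
            raise ValueError("weight matrix shape mismatch")


@dataclass
class Cast:
    """A shrink-wrapped specimen: per grid id a 3D surface point or an
    invalid flag.  Coordinates of invalid ids are NaN."""

    n_rows: int
    n_cols: int
    coords: np.ndarray  # (n_points, 3) µm; NaN rows where invalid
    valid: np.ndarray  # (n_points,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.n_rows * self.n_cols
        if self.coords.shape != (n, 3):
            raise ValueError(f"expected coords of shape ({n}, 3), got {self.coords.shape}")
        if self.valid.shape != (n,):
            raise ValueError("valid mask shape mismatch")
        if np.any(~np.isfinite(self.coords[self.valid])):
            raise ValueError("valid points must have finite coordinates")

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_ids(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    def copy(self) -> "Cast":
        return Cast(self.n_rows, self.n_cols, self.coords.copy(), self.valid.copy())


def build_grid(n_rows: int, n_cols: int, bbox: tuple[float, float, float, float]) -> GridTemplate:
    """Uniform lattice of ``n_rows x n_cols`` points filling ``bbox``.

    ``bbox = (umin, umax, vmin, vmax)`` in µm; u varies along columns and
    v along rows, so id ``r * n_cols + c`` sits at ``(u_c, v_r)``.
    """
    umin, umax, vmin, vmax = (float(b) for b in bbox)
    if not (umax > umin and vmax > vmin):
        raise ValueError(f"degenerate bounding box {bbox}")
    u = np.linspace(umin, umax, n_cols)
    v = np.linspace(vmin, vmax, n_rows)
    vv, uu = np.meshgrid(v, u, indexing="ij")
    return GridTemplate(n_rows, n_cols, np.column_stack([uu.ravel(), vv.ravel()]))


def tps_warp(
    grid: GridTemplate, pairs: LandmarkPairSet, smoothing: float = 0.0
) -> GridTemplate:
    """Thin-plate-spline warp of the grid driven by landmark pairs.

    With ``smoothing == 0`` the spline interpolates the landmarks exactly
    and reproduces affine correspondences exactly (the polynomial part of
    the TPS kernel).  Ids are preserved; only positions move.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    try:
        interp = RBFInterpolator(
            pairs.source, pairs.target, kernel="thin_plate_spline", smoothing=smoothing
        )
        warped = interp(grid.points)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by LandmarkPairSet
        raise ValueError(f"singular thin-plate-spline system: {exc}") from exc
    return grid.with_points(warped)


def _mean_value_coordinates(points: np.ndarray, cage: np.ndarray) -> np.ndarray:
    """Mean-value coordinates of interior ``points`` w.r.t. polygon ``cage``.

    Floater's tangent formula: with s_j = v_j - p, r_j = |s_j| and
    t_j = tan(angle(s_j, s_{j+1}) / 2) = (r_j r_{j+1} - s_j . s_{j+1}) / cross(s_j, s_{j+1}),
    the unnormalised weight of vertex j is (t_{j-1} + t_j) / r_j.
    """
    n_v = len(cage)
    s = cage[None, :, :] - points[:, None, :]  # (N, V, 2)
    r = np.linalg.norm(s, axis=2)  # (N, V)
    if np.any(r < 1e-12):
        raise ValueError("grid point coincides with a cage vertex")
    s_next = np.roll(s, -1, axis=1)
    r_next = np.roll(r, -1, axis=1)
    cross = s[:, :, 0] * s_next[:, :, 1] - s[:, :, 1] * s_next[:, :, 0]
    dot = (s * s_next).sum(axis=2)
    if np.any(np.abs(cross) < 1e-12 * np.maximum(r * r_next, 1.0)) and np.any(dot < 0):
        raise ValueError("grid point lies on a cage edge")
    tan_half = (r * r_next - dot) / cross
    w = (np.roll(tan_half, 1, axis=1) + tan_half) / r
    total = w.sum(axis=1, keepdims=True)
    return w / total


def cage_bind(grid: GridTemplate, cage_polygon: np.ndarray) -> DeformCage:
    """Bind a grid to a closed control polygon via mean-value coordinates.

    Every grid point must lie strictly inside the (simple, non
    self-intersecting) polygon.  The binding has linear precision: an
    affine motion of the cage moves every bound point by the same affine
    map, and the unchanged cage reproduces the grid exactly.
    """
    cage_polygon = np.asarray(cage_polygon, dtype=float)
    if cage_polygon.ndim != 2 or cage_polygon.shape[1] != 2 or len(cage_polygon) < 3:
        raise ValueError("cage must be a polygon of at least 3 2D vertices")
    poly = Polygon(cage_polygon)
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("cage polygon is self-intersecting")
    inside = shapely.contains_xy(poly, grid.points[:, 0], grid.points[:, 1])
    if not inside.all():
        n_out = int((~inside).sum())
        raise ValueError(f"{n_out} grid points lie outside (or on) the cage polygon")
    weights = _mean_value_coordinates(grid.points, cage_polygon)
    return DeformCage(grid, cage_polygon, weights)


def cage_deform(binding: DeformCage, moved_cage: np.ndarray) -> GridTemplate:
    """Apply a cage motion to the bound grid: ``points = weights @ moved_cage``."""
    moved_cage = np.asarray(moved_cage, dtype=float)
    if moved_cage.shape != binding.cage.shape:
        raise ValueError("moved cage must have the same vertex count as the binding")
    return binding.grid.with_points(binding.weights @ moved_cage)


def _point_bins(points: np.ndarray, origin: np.ndarray, bin_size: float, n_bins: np.ndarray):
    """CSR-style binning of 2D points onto a uniform bin lattice."""
    ij = np.floor((points - origin) / bin_size).astype(np.int64)
    ij = np.clip(ij, 0, n_bins - 1)
    keys = ij[:, 1] * n_bins[0] + ij[:, 0]
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    starts = np.searchsorted(sorted_keys, np.arange(n_bins[0] * n_bins[1]))
    ends = np.searchsorted(sorted_keys, np.arange(n_bins[0] * n_bins[1]), side="right")
    return order, starts, ends


def shrink_wrap(grid: GridTemplate, mesh: TriangleMesh) -> Cast:
    """Project the grid onto the mesh by parallel projection along z.

    For each grid point (u, v) a ray x = u, y = v parallel to the z axis
    is intersected with every overlapping triangle; the point becomes
    ``(u, v, z*)`` with ``z*`` the maximum-z intersection (the outermost
    surface toward the viewer).  Points whose ray misses the mesh are
    invalid.  The output (x, y) equal the grid coordinates exactly, and
    coincident hits (rays through shared edges) collapse naturally under
    the max.
    """
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    pts = grid.points
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    tri2d = tri[:, :, :2]
    tri_z = tri[:, :, 2]

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    # bin size ~ median triangle bbox edge keeps candidate lists short
    tlo = tri2d.min(axis=1)
    thi = tri2d.max(axis=1)
    med = np.median(np.maximum(thi - tlo, 1e-9))
    bin_size = float(max(med, span.max() / 512, 1e-9))
    n_bins = np.maximum((span / bin_size).astype(np.int64) + 1, 1)
    order, starts, ends = _point_bins(pts, lo, bin_size, n_bins)

    scale2 = float(np.median((thi - tlo).prod(axis=1)) + 1e-30)
    area_eps = 1e-12 * max(scale2, 1.0)

    z_best = np.full(grid.n_points, -np.inf)
    a, b, c = tri2d[:, 0], tri2d[:, 1], tri2d[:, 2]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    ilo = np.clip(np.floor((tlo - lo) / bin_size).astype(np.int64), 0, n_bins - 1)
    ihi = np.clip(np.floor((thi - lo) / bin_size).astype(np.int64), 0, n_bins - 1)
    nx = int(n_bins[0])
    for t in range(len(tri)):
        if abs(det[t]) < area_eps:
            continue  # vertical or degenerate triangle: no graph area
        cand_chunks = []
        for iy in range(ilo[t, 1], ihi[t, 1] + 1):
            k0 = iy * nx + ilo[t, 0]
            k1 = iy * nx + ihi[t, 0]
            s, e = starts[k0], ends[k1]
            if e > s:
                cand_chunks.append(order[s:e])
        if not cand_chunks:
            continue
        cand = np.concatenate(cand_chunks)
        p = pts[cand]
        inv = 1.0 / det[t]
        w1 = ((p[:, 0] - a[t, 0]) * (c[t, 1] - a[t, 1]) - (p[:, 1] - a[t, 1]) * (c[t, 0] - a[t, 0])) * inv
        w2 = ((b[t, 0] - a[t, 0]) * (p[:, 1] - a[t, 1]) - (b[t, 1] - a[t, 1]) * (p[:, 0] - a[t, 0])) * inv
        w0 = 1.0 - w1 - w2
        eps = 1e-9
        hit = (w0 >= -eps) & (w1 >= -eps) & (w2 >= -eps)
        if not hit.any():
            continue
        idx = cand[hit]
        z = w0[hit] * tri_z[t, 0] + w1[hit] * tri_z[t, 1] + w2[hit] * tri_z[t, 2]
        np.maximum.at(z_best, idx, z)

    valid = np.isfinite(z_best)
    coords = np.full((grid.n_points, 3), np.nan)
    coords[valid, 0] = pts[valid, 0]
    coords[valid, 1] = pts[valid, 1]
    coords[valid, 2] = z_best[valid]
    return Cast(grid.n_rows, grid.n_cols, coords, valid)


def wrap_specimen(
    mesh: TriangleMesh,
    template: GridTemplate,
    landmark_pairs: LandmarkPairSet | None = None,
    cage_binding: DeformCage | None = None,
    moved_cage: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> Cast:
    """Adjust the template grid to a specimen, then shrink-wrap it.

    Exactly one adjustment route may be given: landmark pairs (TPS warp)
    or a cage binding plus moved cage vertices (mean-value coordinates).
    With neither, the template is projected unchanged.  The whole
    composition is deterministic.
    """
    if landmark_pairs is not None and cage_binding is not None:
        raise ValueError("give either landmark pairs or a cage motion, not both")
    if landmark_pairs is not None:
        grid = tps_warp(template, landmark_pairs, smoothing=smoothing)
    elif cage_binding is not None:
        if moved_cage is None:
            raise ValueError("cage route requires moved cage vertices")
        grid = cage_deform(cage_binding, moved_cage)
    else:
        grid = template
    return shrink_wrap(grid, mesh)
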