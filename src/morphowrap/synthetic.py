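"""Synthetic half-body populations with known group effects.

Every downstream stage of the workflow can be exercised without any
scanned data: this module emulates two treatment groups of bilaterally
halved, smooth, convex-ish body surfaces at millimetre scale — a
flat-topped half-superellipsoid carapace with a tapered tail spine and a
small head bump, sampled as a single-valued height field z(x, y) over its
silhouette (which guarantees an unambiguous parallel-projection wrap).

Group structure mirrors a predator-induction experiment: the treated
ideal is the control ideal under a *global size factor* plus *localised
shape offsets* (posterior spine drag, head-region bump).  Individuals
vary around their group ideal by a smooth correlated positional field
(biological variation) plus fine-scale independent jitter (meshing /
projection roughness), and every cast is randomly rigidly displaced so
the superimposition stage has real work to do.

The generator also records the *truth*: the noiseless displacement field
between the two group ideals after the partial (size-retaining)
Procrustes fit, against which an analysis of the noisy population can be
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .stats import DisplacementField, displacement_field
from .surface import IntensityVolume, TriangleMesh
from .wrap import Cast, GridTemplate, LandmarkPairSet, build_grid

__all__ = [
    "BodyParams",
    "LocalBump",
    "GroupEffect",
    "SyntheticStudy",
    "height_field",
    "make_half_body",
    "default_grid_bbox",
    "ideal_cast",
    "make_population",
    "voxelize_height_field",
]


@dataclass
class BodyParams:
    """Geometry of the half body (all lengths in µm).

    The carapace is the upper half of a superellipsoid: semi-axes
    ``body_length / 2`` antero-posteriorly (y), ``body_height / 2``
    dorso-ventrally (x) and ``half_width`` laterally (z), with exponent
    >= 2 (larger exponents give the flat-topped, box-ish silhouette of a
    water-flea carapace).  A tapered spine ridge extends posteriorly and
    a smooth bump marks the head region.
    """

    body_length: float = 2500.0
    body_height: float = 1600.0
    half_width: float = 400.0
    spine_length: float = 500.0
    head_bump_amplitude: float = 120.0
    exponent: float = 4.0

    def __post_init__(self) -> None:
        for name in ("body_length", "body_height", "half_width", "spine_length"):
            if getattr(self, name) < 0 or (
                name in ("body_length", "body_height", "half_width")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.head_bump_amplitude < 0:
            raise ValueError("head_bump_amplitude must be non-negative")
        if self.exponent < 2:
            raise ValueError("superellipse exponent must be >= 2")

    @property
    def semi_y(self) -> float:
        return self.body_length / 2.0

    @property
    def semi_x(self) -> float:
        return self.body_height / 2.0


@dataclass
class LocalBump:
    """A Gaussian lateral (z) offset localised around a template position."""

    center: tuple[float, float]  # (x, y) µm in the template frame
    sigma: float  # µm
    amplitude: float  # µm along z


@dataclass
class GroupEffect:
    """Deformation taking the control ideal to the treated ideal.

    ``global_scale`` is a uniform size factor about the cast centroid;
    ``spine_elongation`` drags the posterior body margin further
    posteriorly (the carapace follows the elongating spine);
    ``local_bumps`` add lateral offsets in named regions.  Individual
    variation combines a smooth correlated field of standard deviation
    ``individual_noise_sd`` per axis with independent per-point jitter of
    standard deviation ``fine_noise_sd`` (surface-meshing and projection
    roughness).
    """

    global_scale: float = 1.1
    spine_elongation: float = 1.3
    local_bumps: list[LocalBump] = field(
        default_factory=lambda: [LocalBump(center=(200.0, 900.0), sigma=150.0, amplitude=20.0)]
    )
    individual_noise_sd: float = 5.0
    fine_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.global_scale <= 0 or self.spine_elongation <= 0:
            raise ValueError("effect factors must be positive")
        if self.individual_noise_sd < 0 or self.fine_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def identity(cls, individual_noise_sd: float = 0.0, fine_noise_sd: float = 0.0) -> "GroupEffect":
        return cls(
            global_scale=1.0,
            spine_elongation=1.0,
            local_bumps=[],
            individual_noise_sd=individual_noise_sd,
            fine_noise_sd=fine_noise_sd,
        )


def height_field(params: BodyParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lateral height z >= 0 of the half body over the (x, y) plane.

    Zero outside the silhouette.  By construction z is single-valued, so
    a parallel z-projection meets the surface at exactly one point over
    the silhouette interior.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    e = params.exponent
    s = np.abs(x / params.semi_x) ** e + np.abs(y / params.semi_y) ** e
    body = params.half_width * np.maximum(0.0, 1.0 - s) ** (1.0 / e)
    h = body
    if params.spine_length > 0:
        # tapered ridge running posteriorly from 80 % of the body semi-axis
        t = (-y - 0.8 * params.semi_y) / (0.2 * params.semi_y + params.spine_length)
        in_spine = (t >= 0.0) & (t <= 1.0)
        w = 0.09 * params.body_height * (1.0 - 0.9 * np.clip(t, 0.0, 1.0))
        profile = np.maximum(0.0, 1.0 - (x / np.maximum(w, 1e-9)) ** 2)
        spine = 0.35 * params.half_width * (1.0 - np.clip(t, 0.0, 1.0)) * profile
        h = np.maximum(h, np.where(in_spine, spine, 0.0))
    if params.head_bump_amplitude > 0:
        xh, yh = 0.25 * params.semi_x, 0.7 * params.semi_y
        sigma = 0.12 * params.body_length
        bump = params.head_bump_amplitude * np.exp(
            -((x - xh) ** 2 + (y - yh) ** 2) / (2.0 * sigma**2)
        )
        # fade the bump out near the silhouette margin so it never extends it
        gate = np.clip(body / (0.2 * params.half_width), 0.0, 1.0)
        h = h + bump * gate
    return h


def canonical_landmarks(params: BodyParams) -> dict[str, tuple[float, float]]:
    """Named 2D anchor points used to adjust the grid to a specimen."""
    ax, ay = params.semi_x, params.semi_y
    return {
        "spine_tip": (0.0, -(ay + params.spine_length)),
        "head_vertex": (0.0, ay),
        "rostrum_tip": (-0.55 * ax, 0.7 * ay),
        "dorsal_margin": (0.95 * ax, 0.0),
        "ventral_margin": (-0.95 * ax, 0.0),
        "heart_indentation": (0.8 * ax, 0.45 * ay),
    }


def landmark_pairs(
    base: BodyParams, specimen_landmarks: dict[str, tuple[float, float]]
) -> LandmarkPairSet:
    """Pair the template's canonical landmarks with a specimen's."""
    template = canonical_landmarks(base)
    names = sorted(set(template) & set(specimen_landmarks))
    if len(names) < 3:
        raise ValueError("need at least 3 shared landmark names")
    src = np.array([template[n] for n in names])
    dst = np.array([specimen_landmarks[n] for n in names])
    return LandmarkPairSet(src, dst, names=names)


def make_half_body(
    params: BodyParams, n_u: int = 121, n_v: int = 181
) -> tuple[TriangleMesh, dict[str, tuple[float, float]]]:
    """Triangulate the height field into a mesh, with canonical landmarks.

    The mesh covers grid cells whose corners all lie strictly inside the
    silhouette, so its antero-posterior extent approaches
    ``body_length + spine_length`` to within one mesh edge.
    """
    ax, ay = params.semi_x, params.semi_y
    x = np.linspace(-1.02 * ax, 1.02 * ax, n_u)
    y = np.linspace(-1.02 * (ay + params.spine_length), 1.02 * ay, n_v)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    h = height_field(params, xx, yy)
    inside = h > 0.0
    idx = -np.ones(inside.shape, dtype=np.int64)
    idx[inside] = np.arange(int(inside.sum()))
    verts = np.column_stack([xx[inside], yy[inside], h[inside]])
    faces = []
    for i in range(len(y) - 1):
        for j in range(len(x) - 1):
            a, b = idx[i, j], idx[i, j + 1]
            c, d = idx[i + 1, j], idx[i + 1, j + 1]
            if a >= 0 and b >= 0 and d >= 0:
                faces.append((a, b, d))
            if a >= 0 and d >= 0 and c >= 0:
                faces.append((a, d, c))
    if not faces:
        raise ValueError("degenerate body: empty silhouette")
    return TriangleMesh(verts, np.array(faces)), canonical_landmarks(params)


def default_grid_bbox(params: BodyParams, margin: float = 0.95) -> tuple[float, float, float, float]:
    """Template grid bounding box: the carapace body region, slightly shrunk.

    With the default exponent the superellipse silhouette fills ~97 % of
    this box, so shrink-wrapped casts keep well above 90 % of their grid
    points valid.  The protruding spine itself lies outside the box; its
    elongation shows up as posterior-margin displacement.
    """
    ax, ay = params.semi_x, params.semi_y
    return (-margin * ax, margin * ax, -margin * ay, margin * ay)


def ideal_cast(grid: GridTemplate, params: BodyParams) -> Cast:
    """Noise-free cast: the height field sampled at the grid points."""
    u, v = grid.points[:, 0], grid.points[:, 1]
    h = height_field(params, u, v)
    valid = h > 0.0
    coords = np.full((grid.n_points, 3), np.nan)
    coords[valid, 0] = u[valid]
    coords[valid, 1] = v[valid]
    coords[valid, 2] = h[valid]
    return Cast(grid.n_rows, grid.n_cols, coords, valid)


def _apply_effect(cast: Cast, grid: GridTemplate, params: BodyParams, effect: GroupEffect) -> Cast:
    """Deform a cast into its treated counterpart.

    Offsets are evaluated at the *template* grid positions, so the same
    grid id receives the same deformation on every specimen (the grid
    follows the specimen's landmarks, hence validity is unchanged).
    """
    coords = cast.coords.copy()
    valid = cast.valid
    centroid = coords[valid].mean(axis=0)
    coords[valid] = centroid + effect.global_scale * (coords[valid] - centroid)
    u, v = grid.points[:, 0], grid.points[:, 1]
    if effect.spine_elongation != 1.0 and params.spine_length > 0:
        # drag confined to the posterior margin: the carapace follows the
        # elongating spine root, leaving the body centre untouched
        w = np.clip((-v / params.semi_y - 0.65) / 0.30, 0.0, 1.0) ** 2
        drag = 0.5 * (effect.spine_elongation - 1.0) * params.spine_length
        coords[valid, 1] -= drag * w[valid]
    for bump in effect.local_bumps:
        g = bump.amplitude * np.exp(
            -((u - bump.center[0]) ** 2 + (v - bump.center[1]) ** 2) / (2.0 * bump.sigma**2)
        )
        coords[valid, 2] += g[valid]
    return Cast(cast.n_rows, cast.n_cols, coords, valid.copy())


def _smooth_field(
    rng: np.random.Generator,
    points: np.ndarray,
    sd: float,
    n_modes: int = 40,
    wavelength_range: tuple[float, float] = (300.0, 1500.0),
) -> np.ndarray:
    """Stationary smooth random field with pointwise standard deviation ``sd``.

    A random-phase superposition of plane-wave cosines with random
    directions and wavelengths: spatially smooth and, for tens of modes,
    close to Gaussian at each point.
    """
    if sd == 0.0:
        return np.zeros(len(points))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    lam = rng.uniform(*wavelength_range, n_modes)
    phase = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    k = 2.0 * np.pi / lam
    proj = points[:, 0][:, None] * np.cos(theta) + points[:, 1][:, None] * np.sin(theta)
    return sd * np.sqrt(2.0 / n_modes) * np.cos(k * proj + phase).sum(axis=1)


def _random_rigid(rng: np.random.Generator, max_angle_deg: float, max_shift_um: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    shift = rng.uniform(-max_shift_um, max_shift_um, 3)
    return rot, shift


@dataclass
class SyntheticStudy:
    """A simulated two-group cast study plus its generating truth."""

    grid: GridTemplate
    control: list[Cast]
    treated: list[Cast]
    ideal_control: Cast
    ideal_treated: Cast
    truth: DisplacementField  # noiseless field after partial Procrustes
    params: BodyParams
    effect: GroupEffect
    seed: int | None


def make_population(
    grid: GridTemplate,
    base: BodyParams,
    effect: GroupEffect,
    n_control: int = 10,
    n_treated: int = 9,
    seed: int | None = None,
    max_rigid_angle_deg: float = 15.0,
    max_rigid_shift_um: float = 300.0,
) -> SyntheticStudy:
    """Generate control and treated cast populations with known truth.

    Control casts sample the base body; treated casts sample the base
    body under ``effect``.  Each individual receives its own smooth
    positional field plus fine jitter on every axis, then a random rigid
    displacement.  With the effect set to identity and zero noise, all
    casts are identical up to rigid motion.  Everything is a pure
    function of ``seed``.
    """
    if n_control < 2 or n_treated < 2:
        raise ValueError("need at least 2 individuals per group")
    rng = np.random.default_rng(seed)
    c0 = ideal_cast(grid, base)
    t0 = _apply_effect(c0, grid, base, effect)
    truth = displacement_field(c0, t0, allow_scaling=False)

    def individual(ideal: Cast) -> Cast:
        coords = ideal.coords.copy()
        valid = ideal.valid
        for axis in range(3):
            coords[valid, axis] += _smooth_field(rng, grid.points[valid], effect.individual_noise_sd)
        if effect.fine_noise_sd > 0:
            coords[valid] += rng.normal(0.0, effect.fine_noise_sd, (int(valid.sum()), 3))
        rot, shift = _random_rigid(rng, max_rigid_angle_deg, max_rigid_shift_um)
        coords[valid] = coords[valid] @ rot.T + shift
        return Cast(ideal.n_rows, ideal.n_cols, coords, valid.copy())

    control = [individual(c0) for _ in range(n_control)]
    treated = [individual(t0) for _ in range(n_treated)]
    return SyntheticStudy(grid, control, treated, c0, t0, truth, base, effect, seed)


def default_study_grid(
    params: BodyParams | None = None, n_rows: int = 400, n_cols: int = 320
) -> GridTemplate:
    """The template grid used by the synthetic presets."""
    params = params or BodyParams()
    return build_grid(n_rows, n_cols, default_grid_bbox(params))


def voxelize_height_field(
    params: BodyParams,
    spacing: tuple[float, float, float] = (5.0, 10.0, 10.0),
    intensity: float = 1000.0,
    pad_voxels: int = 2,
) -> IntensityVolume:
    """Binary-ish voxelisation of the solid half body for extract-stage tests.

    The solid occupies ``0 <= z <= height(x, y)``.  Occupancy is
    anti-aliased linearly across one voxel at the upper surface so the
    marching-cubes iso-surface at half intensity lands sub-voxel close to
    the analytic height field.  Optical realism (PSF, noise) is not
    modelled.
    """
    dz, dy, dx = spacing
    ax, ay = params.semi_x, params.semi_y
    x = np.arange(-ax - pad_voxels * dx, ax + pad_voxels * dx + dx / 2, dx)
    y = np.arange(
        -(ay + params.spine_length) - pad_voxels * dy, ay + pad_voxels * dy + dy / 2, dy
    )
    top = params.half_width + params.head_bump_amplitude
    z = np.arange(-pad_voxels * dz, top + pad_voxels * dz + dz / 2, dz)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    h = height_field(params, xx, yy)  # (ny, nx)
    occ_top = np.clip((h[None, :, :] - z[:, None, None]) / dz + 0.5, 0.0, 1.0)
    occ_bottom = np.clip(z[:, None, None] / dz + 0.5, 0.0, 1.0)
    vox = intensity * occ_top * occ_bottom * (h[None, :, :] > 0)
    return IntensityVolume(vox, (dz, dy, dx))
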