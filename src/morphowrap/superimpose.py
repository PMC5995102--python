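"""Procrustes superimposition of casts (start of the *compute* stage).

Casts are least-squares superimposed over translations and proper
rotations — the *partial* Procrustes fit, which deliberately retains
size, since size can itself be the biological signal.  A uniform scale
factor may be enabled to obtain the size-adjusted ("full") fit instead.
Reflections are never permitted: all specimens are same-handed half
bodies.

Missing data are handled by fitting on the intersection of valid ids of
the two point sets and then applying the fitted transform to every valid
point of the moving set; no nearest-neighbour matching is involved,
correspondence comes entirely from the grid ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wrap import Cast

__all__ = ["ProcrustesResult", "AlignedGroup", "procrustes", "align_group"]

#: Minimum number of shared valid points for a determined 3D fit.
MIN_COMMON_POINTS = 3


def _coords_valid(obj) -> tuple[np.ndarray, np.ndarray]:
    """Accept a Cast / MeanModel-like object or a bare (n, 3) array."""
    if hasattr(obj, "coords") and hasattr(obj, "valid"):
        return np.asarray(obj.coords, dtype=float), np.asarray(obj.valid, dtype=bool)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise TypeError("expected a cast-like object or an (n, 3) array")
    return arr, np.all(np.isfinite(arr), axis=1)


@dataclass
class ProcrustesResult:
    """A fitted similarity (or rigid) transform and its residual.

    ``aligned`` holds the moving point set after ``x -> scale * R @ x + t``
    was applied to all of its valid points.  ``distance`` is the partial
    Procrustes distance: the minimal sum of squared point distances over
    the shared valid ids, in µm².
    """

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,) µm
    scale: float  # 1.0 when scaling disabled
    distance: float  # µm²
    aligned: Cast | np.ndarray
    n_common: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation


def procrustes(reference, moving, allow_scaling: bool = False) -> ProcrustesResult:
    """Least-squares superimposition of ``moving`` onto ``reference``.

    The transform (proper rotation + translation, optionally a uniform
    scale) is estimated on the ids valid in both sets and applied to all
    valid points of ``moving``.  With scaling disabled the centroid size
    of the moving configuration is preserved, so the residual reflects
    differences of *form* (shape + size); with scaling enabled it
    reflects shape only.
    """
    ref_coords, ref_valid = _coords_valid(reference)
    mov_coords, mov_valid = _coords_valid(moving)
    if ref_coords.shape != mov_coords.shape:
        raise ValueError("reference and moving must share the same id space")
    common = ref_valid & mov_valid
    n_common = int(common.sum())
    if n_common < MIN_COMMON_POINTS:
        raise ValueError(
            f"need at least {MIN_COMMON_POINTS} shared valid points, got {n_common}"
        )
    x_ref = ref_coords[common]
    x_mov = mov_coords[common]
    mu_ref = x_ref.mean(axis=0)
    mu_mov = x_mov.mean(axis=0)
    xc_ref = x_ref - mu_ref
    xc_mov = x_mov - mu_mov
    ss_mov = float((xc_mov**2).sum())
    if ss_mov <= 0 or float((xc_ref**2).sum()) <= 0:
        raise ValueError("zero-variance configuration")
    cov = xc_mov.T @ xc_ref  # sum of outer products x_mov x_ref^T
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # degenerate (e.g. collinear) configuration
        raise ValueError("degenerate configuration: rotation undetermined")
    signs = np.array([1.0, 1.0, d])
    rotation = (vt.T * signs) @ u.T
    if allow_scaling:
        scale = float((s * signs).sum() / ss_mov)
        if scale <= 0:
            raise ValueError("non-positive optimal scale")
    else:
        scale = 1.0
    translation = mu_ref - scale * rotation @ mu_mov
    fitted = scale * x_mov @ rotation.T + translation
    distance = float(((fitted - x_ref) ** 2).sum())

    if isinstance(moving, Cast):
        coords = np.full_like(mov_coords, np.nan)
        coords[mov_valid] = scale * mov_coords[mov_valid] @ rotation.T + translation
        aligned = Cast(moving.n_rows, moving.n_cols, coords, mov_valid.copy())
    else:
        coords = np.full_like(mov_coords, np.nan)
        coords[mov_valid] = scale * mov_coords[mov_valid] @ rotation.T + translation
        aligned = coords
    return ProcrustesResult(rotation, translation, scale, distance, aligned, n_common)


@dataclass
class AlignedGroup:
    """Casts of one treatment group superimposed onto a shared prototype."""

    casts: list[Cast]
    prototype_index: int
    transforms: list[ProcrustesResult | None]  # None for the prototype itself

    def __len__(self) -> int:
        return len(self.casts)

    def coords_stack(self) -> np.ndarray:
        """(n_casts, n_points, 3) stacked coordinates (NaN where invalid)."""
        return np.stack([c.coords for c in self.casts])

    def common_valid(self) -> np.ndarray:
        """Ids valid in every member of the group."""
        mask = self.casts[0].valid.copy()
        for c in self.casts[1:]:
            mask &= c.valid
        return mask


def align_group(
    casts: list[Cast],
    prototype: int | Cast = 0,
    allow_scaling: bool = False,
) -> AlignedGroup:
    """Align every cast independently onto one prototype (star alignment).

    ``prototype`` is either an index into ``casts`` (that cast is left
    unchanged) or an external cast/model to align against.  The result is
    independent of the listing order of the other casts.
    """
    if not casts:
        raise ValueError("empty group")
    if isinstance(prototype, int):
        if not 0 <= prototype < len(casts):
            raise ValueError("prototype index out of range")
        proto_obj = casts[prototype]
        proto_idx = prototype
    else:
        proto_obj = prototype
        proto_idx = -1
    aligned: list[Cast] = []
    transforms: list[ProcrustesResult | None] = []
    for i, cast in enumerate(casts):
        if i == proto_idx:
            aligned.append(cast.copy())
            transforms.append(None)
            continue
        res = procrustes(proto_obj, cast, allow_scaling=allow_scaling)
        aligned.append(res.aligned)
        transforms.append(res)
    return AlignedGroup(aligned, proto_idx, transforms)
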