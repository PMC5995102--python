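"""Per-point confidence ellipsoids and overlap classification.

For every tested grid id, each group contributes an axis-aligned
ellipsoid centred on the group-mean position of that point, with the
per-axis 95 % confidence-interval half-widths as radii.  Where the two
groups' ellipsoids do not intersect the point is classified as
significantly displaced (rendered black); overlap is rendered purple.
A label-permutation check — repeatedly exchanging half of the casts
between the treatments while keeping group sizes constant — should turn
a genuine group separation into near-complete overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .superimpose import AlignedGroup, align_group
from .wrap import Cast

__all__ = [
    "EllipsoidSet",
    "OverlapResult",
    "confidence_ellipsoids",
    "ellipsoid_overlap",
    "overlap_map",
    "permute_and_test",
]

COLOR_NO_OVERLAP = "black"
COLOR_OVERLAP = "purple"

_BISECT_TOL = 1e-12
_TANGENT_TOL = 1e-9


@dataclass
class EllipsoidSet:
    """Axis-aligned confidence ellipsoids, one per tested grid id."""

    n_rows: int
    n_cols: int
    centers: np.ndarray  # (n_points, 3) µm, NaN where untested
    radii: np.ndarray  # (n_points, 3) µm >= 0, NaN where untested
    valid: np.ndarray  # (n_points,) bool
    n: int  # group size
    ci_level: float


@dataclass
class OverlapResult:
    """Per-id overlap verdicts between two ellipsoid sets."""

    overlap: np.ndarray  # (n_points,) bool
    valid: np.ndarray  # (n_points,) bool

    def colors(self) -> np.ndarray:
        out = np.empty(len(self.overlap), dtype=object)
        out[self.valid & self.overlap] = COLOR_OVERLAP
        out[self.valid & ~self.overlap] = COLOR_NO_OVERLAP
        return out

    def fraction_overlapping(self) -> float:
        if not self.valid.any():
            return float("nan")
        return float(self.overlap[self.valid].mean())


def confidence_ellipsoids(
    group, ci_level: float = 0.95, kind: str = "mean"
) -> EllipsoidSet:
    """Confidence ellipsoids of a group's aligned casts.

    Per tested id and axis the centre is the group mean and the radius is
    the t-based confidence half-width: ``t_{1-(1-ci)/2, n-1} * s / sqrt(n)``
    for the CI of the mean (``kind='mean'``) or ``t * s`` for the
    prediction-style interval of an observation (``kind='observation'``).
    Zero per-axis variance yields a degenerate zero radius.
    """
    if not 0 <= ci_level < 1:
        raise ValueError("ci_level must lie in [0, 1)")
    if kind not in ("mean", "observation"):
        raise ValueError("kind must be 'mean' or 'observation'")
    casts = group.casts if isinstance(group, AlignedGroup) else list(group)
    n = len(casts)
    if n < 2:
        raise ValueError("need at least 2 casts per group for confidence radii")
    first = casts[0]
    valid = first.valid.copy()
    for c in casts[1:]:
        valid &= c.valid
    stack = np.stack([c.coords for c in casts])  # (n, N, 3)
    centers = np.full((first.n_points, 3), np.nan)
    radii = np.full((first.n_points, 3), np.nan)
    sub = stack[:, valid, :]
    centers[valid] = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    tq = float(sps.t.ppf(1.0 - (1.0 - ci_level) / 2.0, df=n - 1)) if ci_level > 0 else 0.0
    factor = tq / np.sqrt(n) if kind == "mean" else tq
    radii[valid] = factor * sd
    return EllipsoidSet(first.n_rows, first.n_cols, centers, radii, valid, n, ci_level)


def _quad(x: np.ndarray, c: np.ndarray, r: np.ndarray) -> float:
    """Ellipsoid quadratic form with degenerate axes collapsed.

    Returns +inf when a zero-radius axis is violated.
    """
    val = 0.0
    for j in range(len(c)):
        d = x[j] - c[j]
        if r[j] == 0.0:
            if d != 0.0:
                return np.inf
        else:
            val += (d / r[j]) ** 2
    return val


def ellipsoid_overlap(c1, r1, c2, r2) -> bool:
    """True iff the two closed axis-aligned ellipsoids intersect.

    Quick accept when either centre lies in the other ellipsoid; quick
    reject when the bounding slabs are disjoint on any axis.  Otherwise
    the second ellipsoid's quadratic form is minimised over the first
    ellipsoid through the one-dimensional Lagrange-multiplier root
    (coordinates decouple for axis-aligned forms), solved by bisection;
    overlap iff the minimum is at most 1.  Touching counts as overlap.
    Zero radii collapse axes (segment / disc / point cases).
    """
    c1 = np.asarray(c1, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("radii must be non-negative")
    d = np.abs(c1 - c2)
    if np.any(d > r1 + r2):  # disjoint bounding slabs
        return False
    # Reduce degenerate axes: a zero radius pins that coordinate.
    budget1 = 1.0
    budget2 = 1.0
    free: list[int] = []
    for j in range(len(c1)):
        z1, z2 = r1[j] == 0.0, r2[j] == 0.0
        if z1 and z2:
            if c1[j] != c2[j]:
                return False
        elif z1:
            budget2 -= ((c1[j] - c2[j]) / r2[j]) ** 2
        elif z2:
            budget1 -= ((c2[j] - c1[j]) / r1[j]) ** 2
        else:
            free.append(j)
    tol = _TANGENT_TOL
    if budget1 < -tol or budget2 < -tol:
        return False
    budget1 = max(budget1, 0.0)
    budget2 = max(budget2, 0.0)
    if not free:
        return True
    cc1, rr1 = c1[free], r1[free]
    cc2, rr2 = c2[free], r2[free]
    q1_at_c2 = float((((cc2 - cc1) / rr1) ** 2).sum())
    q2_at_c1 = float((((cc1 - cc2) / rr2) ** 2).sum())
    if q1_at_c2 <= budget1 + tol or q2_at_c1 <= budget2 + tol:
        return True
    if budget1 == 0.0:  # ellipsoid 1 reduced to the single point cc1
        return q2_at_c1 <= budget2 + tol
    # Minimise q2 over the boundary q1 = budget1 (minimiser lies on the
    # boundary because cc2 is outside that ball and q2 is convex).
    a = 1.0 / rr2**2
    b = 1.0 / rr1**2
    diff = cc2 - cc1

    def constraint(mu: float) -> float:
        denom = a + mu * b
        x_minus_c1 = a * diff / denom
        return float((b * x_minus_c1**2).sum()) - budget1

    lo, hi = 0.0, 1.0
    while constraint(hi) > 0.0:
        hi *= 2.0
        if hi > 1e30:  # pragma: no cover - numerically unreachable
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if constraint(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL * max(1.0, hi):
            break
    mu = 0.5 * (lo + hi)
    denom = a + mu * b
    x = (a * cc2 + mu * b * cc1) / denom
    q2_min = float((a * (x - cc2) ** 2).sum())
    return q2_min <= budget2 * (1.0 + tol) + tol


def overlap_map(set_a: EllipsoidSet, set_b: EllipsoidSet) -> OverlapResult:
    """Per-id overlap verdicts between two ellipsoid sets sharing a grid."""
    if (set_a.n_rows, set_a.n_cols) != (set_b.n_rows, set_b.n_cols):
        raise ValueError("ellipsoid sets do not share a grid template")
    valid = set_a.valid & set_b.valid
    n = len(valid)
    overlap = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(valid)
    ca, ra = set_a.centers[idx], set_a.radii[idx]
    cb, rb = set_b.centers[idx], set_b.radii[idx]
    d = np.abs(ca - cb)
    # vectorised quick paths
    reject = np.any(d > ra + rb, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        qa = np.where(ra > 0, ((cb - ca) / np.where(ra > 0, ra, 1)) ** 2, np.where(d > 0, np.inf, 0.0))
        qb = np.where(rb > 0, ((ca - cb) / np.where(rb > 0, rb, 1)) ** 2, np.where(d > 0, np.inf, 0.0))
    accept = (qa.sum(axis=1) <= 1.0 + _TANGENT_TOL) | (qb.sum(axis=1) <= 1.0 + _TANGENT_TOL)
    verdict = np.where(accept & ~reject, True, False)
    ambiguous = ~reject & ~accept
    for k in np.flatnonzero(ambiguous):
        verdict[k] = ellipsoid_overlap(ca[k], ra[k], cb[k], rb[k])
    overlap[idx] = verdict
    return OverlapResult(overlap, valid)


def permute_and_test(
    casts_a: list[Cast],
    casts_b: list[Cast],
    fraction: float = 0.5,
    n_permutations: int = 3,
    seed: int | None = None,
    ci_level: float = 0.95,
    kind: str = "mean",
    prototype: Cast | None = None,
) -> list[OverlapResult]:
    """Exchange a fraction of casts between treatments and re-test overlap.

    For each permutation, ``floor(fraction * min(nA, nB))`` casts chosen
    at random from each group are swapped with the other group, keeping
    both group sizes constant, and the ellipsoid overlap map is
    recomputed from scratch.  A genuine group effect should dissolve into
    near-complete overlap.  The RNG is fully determined by ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_a, n_b = len(casts_a), len(casts_b)
    n_swap = int(np.floor(fraction * min(n_a, n_b)))
    if n_swap == 0:
        raise ValueError("fraction swaps zero casts")
    rng = np.random.default_rng(seed)
    results: list[OverlapResult] = []
    proto = prototype if prototype is not None else casts_a[0]
    for _ in range(int(n_permutations)):
        pick_a = rng.choice(n_a, size=n_swap, replace=False)
        pick_b = rng.choice(n_b, size=n_swap, replace=False)
        new_a = list(casts_a)
        new_b = list(casts_b)
        for i, j in zip(pick_a, pick_b):
            new_a[i], new_b[j] = casts_b[j], casts_a[i]
        grp_a = align_group(new_a, prototype=proto)
        grp_b = align_group(new_b, prototype=proto)
        ell_a = confidence_ellipsoids(grp_a, ci_level=ci_level, kind=kind)
        ell_b = confidence_ellipsoids(grp_b, ci_level=ci_level, kind=kind)
        results.append(overlap_map(ell_a, ell_b))
    return results
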