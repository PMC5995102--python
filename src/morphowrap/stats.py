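"""Group models, displacement fields and dense point-wise inference.

The inferential core of the workflow: average the aligned casts of each
treatment into a mean model, superimpose the two models to obtain a
per-id displacement field (in µm, with magnitudes via the Euclidean
norm), and test every grid id on every coordinate axis with a two-sided
Wilcoxon/Mann-Whitney rank-sum test.  The resulting dense p-value fields
(three per study: x, y, z) are corrected for multiple testing with the
Storey q-value procedure, which also yields the per-axis null proportion
pi0 and its complement pi1, a lower bound on the fraction of truly
displaced points.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats as sps

from .superimpose import AlignedGroup, procrustes
from .wrap import Cast

__all__ = [
    "MeanModel",
    "DisplacementField",
    "PointwiseTestResult",
    "QValueSlice",
    "QValueSet",
    "mean_model",
    "displacement_field",
    "wilcoxon_map",
    "storey_qvalues",
    "qvalue_set",
    "significance_counts",
]

AXES = ("x", "y", "z")

#: Exact rank-sum null distribution is used up to this combined group size
#: (and only for tie-free samples), mirroring common rank-sum practice.
EXACT_MAX_N = 25

#: Lambda grid for the Storey pi0 estimate: 0, 0.01, ..., 0.95.
PI0_LAMBDA_GRID = np.round(np.arange(0.0, 0.951, 0.01), 2)


@dataclass
class MeanModel:
    """Per-id arithmetic mean of a group's aligned casts.

    An id is valid only where valid in *every* member, so each retained
    id averages the same number of specimens (``n_used``).
    """

    n_rows: int
    n_cols: int
    coords: np.ndarray  # (n_points, 3) µm, NaN where invalid
    valid: np.ndarray  # (n_points,) bool
    n_used: int

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class DisplacementField:
    """Per-id displacement vectors between two superimposed mean models."""

    vectors: np.ndarray  # (n_points, 3) µm, other - reference; NaN where untested
    magnitude: np.ndarray  # (n_points,) µm
    valid: np.ndarray  # (n_points,) bool
    scale: float  # scale applied to the moving model during the fit


@dataclass
class PointwiseTestResult:
    """Dense rank-sum test field: one p-value per tested id per axis."""

    p: np.ndarray  # (n_points, 3), NaN where untested
    tested: np.ndarray  # (n_points,) bool
    n1: int
    n2: int
    exact: np.ndarray  # (n_points, 3) bool, True where the exact null was used

    @property
    def n_tests(self) -> int:
        return int(self.tested.sum()) * 3


@dataclass
class QValueSlice:
    """Storey q-values for one axis."""

    q: np.ndarray
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray


@dataclass
class QValueSet:
    """Per-axis q-value fields over the tested ids."""

    q: np.ndarray  # (n_points, 3), NaN where untested
    pi0: np.ndarray  # (3,)
    pi1: np.ndarray  # (3,)
    tested: np.ndarray  # (n_points,) bool


def _group_casts(group) -> list[Cast]:
    if isinstance(group, AlignedGroup):
        return group.casts
    return list(group)


def mean_model(group) -> MeanModel:
    """Average the x, y and z coordinates of all casts of a group, id-wise."""
    casts = _group_casts(group)
    if not casts:
        raise ValueError("empty group")
    first = casts[0]
    valid = first.valid.copy()
    for c in casts[1:]:
        if (c.n_rows, c.n_cols) != (first.n_rows, first.n_cols):
            raise ValueError("casts do not share a grid template")
        valid &= c.valid
    stack = np.stack([c.coords for c in casts])  # (n, N, 3)
    coords = np.full((first.n_points, 3), np.nan)
    coords[valid] = stack[:, valid, :].mean(axis=0)
    return MeanModel(first.n_rows, first.n_cols, coords, valid, len(casts))


def displacement_field(
    reference_model, other_model, allow_scaling: bool = False
) -> DisplacementField:
    """Superimpose ``other_model`` onto ``reference_model`` and subtract.

    The other model is first Procrustes-fit onto the reference (size
    adjusted only when ``allow_scaling``); per-id differences
    ``other - reference`` and their Euclidean magnitudes are returned in
    µm over the shared valid ids.
    """
    res = procrustes(reference_model, other_model, allow_scaling=allow_scaling)
    ref_coords = np.asarray(reference_model.coords, dtype=float)
    ref_valid = np.asarray(reference_model.valid, dtype=bool)
    aligned = res.aligned
    if isinstance(aligned, Cast):
        other_coords, other_valid = aligned.coords, aligned.valid
    else:
        other_coords = aligned
        other_valid = np.all(np.isfinite(other_coords), axis=1)
    shared = ref_valid & other_valid
    vectors = np.full_like(ref_coords, np.nan)
    vectors[shared] = other_coords[shared] - ref_coords[shared]
    magnitude = np.full(len(ref_coords), np.nan)
    magnitude[shared] = np.linalg.norm(vectors[shared], axis=1)
    return DisplacementField(vectors, magnitude, shared, res.scale)


@lru_cache(maxsize=16)
def _ranksum_null_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the tie-free null.

    Counts subsets of size ``n1`` of ranks 1..n1+n2 by rank-sum via the
    classic partition recurrence, then normalises.
    """
    n = n1 + n2
    max_w = n1 * n2 + n1 * (n1 + 1) // 2
    dp = np.zeros((n1 + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    pmf = dp[n1, n1 * (n1 + 1) // 2 :]
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def ranksum_exact_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Exact two-sided rank-sum p-value for U statistic(s) ``u``.

    Uses the symmetry of the null: p = min(1, 2 P(U <= min(u, n1 n2 - u))).
    """
    cdf = _ranksum_null_cdf(n1, n2)
    u = np.asarray(u)
    u_low = np.minimum(u, n1 * n2 - u).astype(np.int64)
    return np.minimum(1.0, 2.0 * cdf[u_low])


def ranksum_attainable_level(alpha: float, n1: int, n2: int) -> float:
    """P(two-sided exact p < alpha) under the null: the test's actual size.

    The exact rank-sum test is discrete, so the probability of a p-value
    strictly below a nominal cut-off is the largest attainable level
    below it, not the cut-off itself (e.g. 0.0076 rather than 0.01 for
    group sizes 10 and 9).
    """
    cdf = _ranksum_null_cdf(n1, n2)
    u = np.arange(n1 * n2 + 1)
    p = ranksum_exact_p(u, n1, n2)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    return float(pmf[p < alpha].sum())


def wilcoxon_map(group_a, group_b) -> PointwiseTestResult:
    """Two-sided rank-sum tests per id per axis between two aligned groups.

    Each grid id valid in every cast of both groups contributes three
    tests (x, y, z coordinates).  For tie-free samples with combined size
    at most ``EXACT_MAX_N`` the exact null distribution of U is used;
    otherwise a normal approximation with tie and continuity correction.
    """
    casts_a = _group_casts(group_a)
    casts_b = _group_casts(group_b)
    if not casts_a or not casts_b:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(casts_a), len(casts_b)
    first = casts_a[0]
    tested = first.valid.copy()
    for c in casts_a[1:] + casts_b:
        if (c.n_rows, c.n_cols) != (first.n_rows, first.n_cols):
            raise ValueError("casts do not share a grid template")
        tested &= c.valid
    n_points = first.n_points
    p = np.full((n_points, 3), np.nan)
    exact_mask = np.zeros((n_points, 3), dtype=bool)
    if not tested.any():
        return PointwiseTestResult(p, tested, n1, n2, exact_mask)

    a = np.stack([c.coords[tested] for c in casts_a])  # (n1, M, 3)
    b = np.stack([c.coords[tested] for c in casts_b])
    n = n1 + n2
    for axis in range(3):
        data = np.concatenate([a[:, :, axis], b[:, :, axis]], axis=0)  # (n, M)
        ranks = sps.rankdata(data, axis=0)
        u_stat = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0  # U of group A
        # per-column tie detection
        srt = np.sort(data, axis=0)
        has_ties = np.any(np.diff(srt, axis=0) == 0, axis=0)
        p_axis = np.empty(data.shape[1])
        use_exact = (~has_ties) & (n <= EXACT_MAX_N)
        if use_exact.any():
            p_axis[use_exact] = ranksum_exact_p(
                np.rint(u_stat[use_exact]), n1, n2
            )
        if (~use_exact).any():
            cols = ~use_exact
            mu = n1 * n2 / 2.0
            # tie correction term sum(t^3 - t) per column
            tie_term = np.zeros(int(cols.sum()))
            for j, col in enumerate(np.flatnonzero(cols)):
                vals, counts = np.unique(data[:, col], return_counts=True)
                tie_term[j] = float(((counts**3 - counts)).sum())
            sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
            sigma = np.sqrt(np.maximum(sigma2, 0.0))
            z = np.zeros_like(sigma)
            nonzero = sigma > 0
            z[nonzero] = (np.abs(u_stat[cols][nonzero] - mu) - 0.5) / sigma[nonzero]
            z = np.maximum(z, 0.0)
            p_axis[cols] = np.minimum(1.0, special.erfc(z / np.sqrt(2.0)))
        p[tested, axis] = p_axis
        exact_mask[tested, axis] = use_exact
    return PointwiseTestResult(p, tested, n1, n2, exact_mask)


def storey_qvalues(p_values: np.ndarray, pi0: float | None = None) -> QValueSlice:
    """Storey q-values with smoothed pi0 estimation for one axis.

    pi0 is estimated on the lambda grid 0, 0.01, ..., 0.95 as
    ``#{p > lambda} / (m (1 - lambda))``, smoothed by a cubic polynomial
    in lambda, evaluated at the largest lambda, and clipped to (0, 1].
    q-values follow the step-up rule ``q(p_(m)) = pi0 p_(m)``,
    ``q(p_(i)) = min(pi0 m p_(i) / i, q(p_(i+1)))``.  Passing ``pi0=1``
    reduces the procedure to Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    m = len(p)
    if m < 10:
        raise ValueError("too few tests for pi0 smoothing (need at least 10)")
    lam = PI0_LAMBDA_GRID
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    if pi0 is None:
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0_hat = float(np.polyval(coeffs, lam[-1]))
        pi0_hat = float(np.clip(pi0_hat, 1.0 / m, 1.0))
    else:
        pi0_hat = float(pi0)
        if not 0 < pi0_hat <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    raw = pi0_hat * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSlice(q, pi0_hat, 1.0 - pi0_hat, lam, pi0_lam)


def qvalue_set(result: PointwiseTestResult, pi0: float | None = None) -> QValueSet:
    """Storey correction applied per axis (x, y, z fields kept separate)."""
    n_points = result.p.shape[0]
    q = np.full((n_points, 3), np.nan)
    pi0_arr = np.empty(3)
    for axis in range(3):
        sl = storey_qvalues(result.p[result.tested, axis], pi0=pi0)
        q[result.tested, axis] = sl.q
        pi0_arr[axis] = sl.pi0
    return QValueSet(q, pi0_arr, 1.0 - pi0_arr, result.tested.copy())


def significance_counts(result: PointwiseTestResult, p_threshold: float) -> dict[str, int]:
    """Per-axis counts of tested ids with p strictly below the threshold."""
    if not 0 < p_threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    counts = {}
    for axis, name in enumerate(AXES):
        vals = result.p[result.tested, axis]
        counts[name] = int((vals < p_threshold).sum())
    return counts
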