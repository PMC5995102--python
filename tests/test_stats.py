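from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from morphowrap import (
    Cast,
    displacement_field,
    mean_model,
    significance_counts,
    storey_qvalues,
    wilcoxon_map,
)
from morphowrap.stats import ranksum_exact_p


def casts_from_values(values):
    """One 2x2 cast per specimen; the tested id 0 carries the given
    (x, y, z) triple, the remaining ids anchor the grid."""
    casts = []
    for v in values:
        coords = np.array([v, [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        casts.append(Cast(2, 2, coords, np.ones(4, dtype=bool)))
    return casts


def brute_force_two_sided_p(a, b):
    """Enumerate every assignment of the pooled ranks to group A.

    Two-sided p-value: the null probability of a U statistic at least as
    extreme (in either direction) as observed.  Assumes no ties.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = min(u_obs, len(a) * len(b) - u_obs)
    count = total = 0
    for subset in combinations(range(len(pooled)), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        if min(u, len(a) * len(b) - u) <= lo:
            count += 1
        total += 1
    return count / total


class TestMeanModel:
    def test_single_cast_is_its_own_mean(self, rng):
        cast = casts_from_values([[5.0, 6.0, 7.0]])[0]
        model = mean_model([cast])
        np.testing.assert_array_equal(model.coords, cast.coords)
        assert model.n_used == 1

    def test_symmetric_offsets_average_to_midpoint(self):
        a, b = casts_from_values([[0.0, 0.0, 3.0], [0.0, 0.0, -3.0]])
        model = mean_model([a, b])
        np.testing.assert_allclose(model.coords[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_id_invalid_in_any_member_is_invalid_in_model(self):
        casts = casts_from_values([[1.0, 1, 1]] * 5)
        casts[2].valid[0] = False
        casts[2].coords[0] = np.nan
        model = mean_model(casts)
        assert not model.valid[0]
        assert model.valid[1:].all()

    def test_commutes_with_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(5, 12, 3)) * 50
        casts = [Cast(3, 4, c, np.ones(12, bool)) for c in coords]
        rot = Rotation.from_rotvec([0.3, 0.2, -0.4]).as_matrix()
        t = np.array([10.0, -5.0, 2.0])
        moved = [Cast(3, 4, c @ rot.T + t, np.ones(12, bool)) for c in coords]
        m1 = mean_model(casts)
        m2 = mean_model(moved)
        np.testing.assert_allclose(m2.coords, m1.coords @ rot.T + t, atol=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            mean_model([])


class TestDisplacementField:
    def test_identical_models_give_zero_field(self, rng):
        coords = rng.normal(size=(20, 3)) * 100
        cast = Cast(4, 5, coords, np.ones(20, bool))
        field = displacement_field(cast, cast.copy())
        assert np.nanmax(field.magnitude) < 1e-9

    def test_magnitude_obeys_pythagoras(self, rng):
        coords = rng.normal(size=(20, 3)) * 100
        ref = Cast(4, 5, coords, np.ones(20, bool))
        other = Cast(4, 5, coords + rng.normal(size=(20, 3)) * 10, np.ones(20, bool))
        field = displacement_field(ref, other)
        v = field.vectors[field.valid]
        np.testing.assert_allclose(
            field.magnitude[field.valid], np.sqrt((v**2).sum(axis=1)), rtol=1e-9
        )
        # vectors are differences of the *aligned* moving model
        assert field.valid.all()
        assert np.median(field.magnitude) < 30.0  # fit removed gross motion

    def test_pure_size_difference_absorbed_by_scaling_fit(self, rng):
        coords = rng.normal(size=(30, 3)) * 100
        ref = Cast(5, 6, coords, np.ones(30, bool))
        bigger = Cast(5, 6, coords * 1.1, np.ones(30, bool))
        full = displacement_field(ref, bigger, allow_scaling=True)
        assert np.nanmax(full.magnitude) < 1e-9
        partial = displacement_field(ref, bigger, allow_scaling=False)
        assert np.nanmedian(partial.magnitude) > 1.0


class TestWilcoxonMap:
    def test_textbook_separated_triples_give_p_point_one(self):
        group_a = casts_from_values([[1, 1, 1.0], [2, 2, 2.0], [3, 3, 3.0]])
        group_b = casts_from_values([[4, 4, 4.0], [5, 5, 5.0], [6, 6, 6.0]])
        result = wilcoxon_map(group_a, group_b)
        np.testing.assert_allclose(result.p[0], 0.1, atol=1e-12)
        assert result.exact[0].all()

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 3), (5, 4), (5, 5)])
    def test_exact_path_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(5):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            ranks = sps.rankdata(np.concatenate([a, b]))
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            p_impl = ranksum_exact_p(np.array([u]), n1, n2)[0]
            p_oracle = brute_force_two_sided_p(a, b)
            assert np.isclose(p_impl, p_oracle, atol=1e-12)

    def test_exact_path_matches_scipy(self, rng):
        a = rng.normal(size=(10, 50))
        b = rng.normal(size=(9, 50))
        ga = [Cast(5, 10, np.tile(col[:, None], 3), np.ones(50, bool)) for col in a]
        gb = [Cast(5, 10, np.tile(col[:, None], 3), np.ones(50, bool)) for col in b]
        result = wilcoxon_map(ga, gb)
        for j in range(50):
            expected = sps.mannwhitneyu(a[:, j], b[:, j], method="exact").pvalue
            assert np.isclose(result.p[j, 0], expected, atol=1e-12)

    def test_tie_path_matches_scipy_normal_approximation(self, rng):
        a = rng.integers(0, 4, size=(8, 30)).astype(float)
        b = rng.integers(0, 4, size=(7, 30)).astype(float)
        ga = [Cast(5, 6, np.tile(col[:, None], 3), np.ones(30, bool)) for col in a]
        gb = [Cast(5, 6, np.tile(col[:, None], 3), np.ones(30, bool)) for col in b]
        result = wilcoxon_map(ga, gb)
        assert not result.exact[result.tested].any()
        for j in range(30):
            expected = sps.mannwhitneyu(
                a[:, j], b[:, j], method="asymptotic", use_continuity=True
            ).pvalue
            assert np.isclose(result.p[j, 0], expected, atol=1e-10)

    def test_identical_multisets_give_p_one(self):
        vals = [[1, 2, 3.0], [4, 5, 6.0], [7, 8, 9.0]]
        result = wilcoxon_map(casts_from_values(vals), casts_from_values(vals))
        np.testing.assert_allclose(result.p[result.tested], 1.0)

    def test_label_swap_symmetry(self, rng):
        a = [casts_from_values([v])[0] for v in rng.normal(size=(6, 3))]
        b = [casts_from_values([v])[0] for v in rng.normal(size=(5, 3))]
        r1 = wilcoxon_map(a, b)
        r2 = wilcoxon_map(b, a)
        np.testing.assert_allclose(r1.p[r1.tested], r2.p[r2.tested], atol=1e-12)

    def test_untested_where_any_cast_invalid(self):
        a = casts_from_values([[1, 1, 1.0], [2, 2, 2.0]])
        b = casts_from_values([[3, 3, 3.0], [4, 4, 4.0]])
        a[0].valid[0] = False
        a[0].coords[0] = np.nan
        result = wilcoxon_map(a, b)
        assert not result.tested[0]
        assert np.isnan(result.p[0]).all()
        assert result.n_tests == 3 * 3


class TestStoreyQValues:
    def test_uniform_null_pi0_near_one(self, rng):
        p = rng.uniform(size=10_000)
        res = storey_qvalues(p)
        assert 0.90 <= res.pi0 <= 1.0
        assert np.isclose(res.pi1, 1.0 - res.pi0)

    def test_mixture_recovers_null_fraction(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-4, 3000), rng.uniform(0, 1, 7000)])
        res = storey_qvalues(p)
        assert 0.6 <= res.pi0 <= 0.8

    def test_all_tiny_pvalues_bounded_and_monotone(self):
        p = np.full(1000, 1e-8)
        res = storey_qvalues(p)
        assert np.all(res.q <= res.pi0 * 1000 * 1e-8 + 1e-15)
        assert np.all(res.q >= 0)

    def test_pi0_one_reduces_to_benjamini_hochberg(self, rng):
        p = rng.uniform(size=500)
        res = storey_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(res.q, bh, atol=1e-12)

    def test_q_order_consistent_with_p(self, rng):
        p = rng.uniform(size=2000) ** 2
        res = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.q[order]) >= -1e-15)
        assert res.q.max() <= 1.0 + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="within"):
            storey_qvalues(np.array([0.5, 1.5] + [0.1] * 10))
        with pytest.raises(ValueError, match="too few"):
            storey_qvalues(np.array([0.5] * 9))


class TestSignificanceCounts:
    def test_counting_against_threshold(self):
        a = casts_from_values([[0.0, 0, 0]] * 5)
        b = casts_from_values([[1.0, 1, 1]] * 5)
        result = wilcoxon_map(a, b)
        # fully separated groups at one id: exact p = 2/C(10,5) ~ 0.0079
        counts = significance_counts(result, 0.01)
        assert counts == {"x": 1, "y": 1, "z": 1}
        assert significance_counts(result, 0.001) == {"x": 0, "y": 0, "z": 0}
        full = significance_counts(result, 1.0)
        assert full == {"x": 1, "y": 1, "z": 1}
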