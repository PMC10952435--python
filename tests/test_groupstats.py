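"""Group comparisons: omnibus tests, pairwise procedures, letter displays."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from starchgran import (
    GroupSample,
    TestKind as StatTest,
    choose_test,
    compact_letters,
    compare_groups,
    kruskal_wallis,
    one_way_anova,
    pairwise_t,
    tukey_all_pairs,
)
from starchgran.groupstats import nemenyi_rank_all_pairs


def groups_of(*arrays):
    return [GroupSample(str(i), np.asarray(a, float)) for i, a in enumerate(arrays)]


def anova_by_hand(arrays):
    """Two-line textbook computation: between-MS / within-MS."""
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    f = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    p = stats.f.sf(f, k - 1, n_total - k)
    return f, p


class TestAnova:
    def test_equal_means_give_zero_f(self):
        res = one_way_anova(groups_of([1, 2, 3], [1, 2, 3]))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_within_variance_separated_means(self):
        res = one_way_anova(groups_of([0, 0], [1, 1]))
        assert res.degenerate
        assert res.pvalue < 1e-12

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(7)
        arrays = [rng.normal(m, 1, 5) for m in (0.0, 0.5, 2.0)]
        res = one_way_anova(groups_of(*arrays))
        f, p = anova_by_hand(arrays)
        assert res.statistic == pytest.approx(f)
        assert res.pvalue == pytest.approx(p)


class TestKruskalWallis:
    def test_hand_value_no_ties(self):
        # H = 12/(N(N+1))·Σ R_j²/n_j − 3(N+1) with rank sums 6 and 15
        res = kruskal_wallis(groups_of([1, 2, 3], [4, 5, 6]))
        assert res.statistic == pytest.approx(3.857, abs=5e-4)

    def test_rank_invariances(self):
        base = groups_of([1.0, 5.0, 2.0], [7.0, 3.0, 9.0])
        h0 = kruskal_wallis(base).statistic
        # permuting observations within groups
        perm = groups_of([2.0, 1.0, 5.0], [9.0, 7.0, 3.0])
        assert kruskal_wallis(perm).statistic == pytest.approx(h0)
        # strictly monotone transform of everything
        trans = groups_of(np.exp([1.0, 5.0, 2.0]), np.exp([7.0, 3.0, 9.0]))
        assert kruskal_wallis(trans).statistic == pytest.approx(h0)

    def test_all_identical_is_null(self):
        res = kruskal_wallis(groups_of([2, 2, 2], [2, 2, 2]))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0


class TestTukey:
    def test_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        pmat = tukey_all_pairs(groups_of(a, b))
        _, p_pooled = stats.ttest_ind(a, b, equal_var=True)
        assert pmat[0, 1] == pytest.approx(p_pooled, rel=1e-6)

    def test_identical_groups_all_one(self):
        pmat = tukey_all_pairs(groups_of([1, 2, 3], [1, 2, 3], [1, 2, 3]))
        np.testing.assert_allclose(pmat, 1.0)

    def test_adjustment_never_below_unadjusted(self):
        rng = np.random.default_rng(13)
        arrays = [rng.normal(m, 1, 4) for m in (0.0, 0.8, 1.6)]
        pmat = tukey_all_pairs(groups_of(*arrays))
        assert np.allclose(pmat, pmat.T)
        np.testing.assert_allclose(np.diag(pmat), 1.0)
        for i, j in itertools.combinations(range(3), 2):
            # unadjusted pooled-variance pairwise p as the oracle floor
            _, p_raw = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
            assert pmat[i, j] >= p_raw - 1e-12


class TestPairwiseT:
    def test_identical_groups(self):
        t, p = pairwise_t(GroupSample("a", [1.0, 2.0, 3.0]),
                          GroupSample("b", [1.0, 2.0, 3.0]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = GroupSample("a", [1.0, 2.0, 2.5])
        b = GroupSample("b", [3.0, 4.0, 5.5])
        t_ab, p_ab = pairwise_t(a, b)
        t_ba, p_ba = pairwise_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_welch_formula(self):
        x = np.array([10.0, 12.0, 11.0, 14.0])
        y = np.array([8.0, 9.5, 7.0])
        t, p = pairwise_t(GroupSample("x", x), GroupSample("y", y))
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)


class TestChooseTest:
    def test_clean_normal_groups_choose_anova(self):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(m, 1, 6) for m in (0, 1, 2)]
        assert choose_test(groups_of(*arrays)) is StatTest.ANOVA_TUKEY

    def test_extreme_outlier_switches_to_ranks(self):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(0, 1, 6) for _ in range(3)]
        arrays[0][0] = 80.0
        assert choose_test(groups_of(*arrays)) is StatTest.KW_RANKS

    def test_deterministic_given_data(self):
        arrays = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]
        first = choose_test(groups_of(*arrays))
        assert all(choose_test(groups_of(*arrays)) is first for _ in range(3))


class TestCompactLetters:
    def test_all_nonsignificant_is_single_letter(self):
        letters = compact_letters(np.ones((4, 4)), alpha=0.05)
        assert set(letters.values()) == {"a"}

    def test_all_significant_gives_distinct_letters(self):
        pmat = np.zeros((4, 4))
        np.fill_diagonal(pmat, 1.0)
        letters = compact_letters(pmat, alpha=0.05)
        assert sorted(letters.values()) == ["a", "b", "c", "d"]

    def test_three_group_worked_example(self):
        pmat = np.array([
            [1.0, 0.001, 0.2],
            [0.001, 1.0, 0.04],
            [0.2, 0.04, 1.0],
        ])
        letters = compact_letters(pmat, alpha=0.05, labels=["g1", "g2", "g3"])
        assert letters == {"g1": "a", "g2": "b", "g3": "a"}

    def test_asymmetric_matrix_rejected(self):
        pmat = np.array([[1.0, 0.1], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            compact_letters(pmat)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_sharing_a_letter_encodes_nonsignificance_exhaustively(self, k):
        rng = np.random.default_rng(17)
        for _ in range(50):
            raw = rng.uniform(0, 0.2, size=(k, k))
            pmat = (raw + raw.T) / 2
            np.fill_diagonal(pmat, 1.0)
            letters = compact_letters(pmat, alpha=0.05,
                                      labels=[str(i) for i in range(k)])
            for i, j in itertools.combinations(range(k), 2):
                shared = set(letters[str(i)]) & set(letters[str(j)])
                assert bool(shared) == (pmat[i, j] > 0.05), (pmat, letters)


class TestCompareGroups:
    def test_separated_groups_reject_under_both_routes(self):
        rng = np.random.default_rng(3)
        arrays = [rng.normal(m, 0.5, 4) for m in (0.0, 10.0, 20.0)]
        g = groups_of(*arrays)
        for test in (StatTest.ANOVA_TUKEY, StatTest.KW_RANKS):
            res = compare_groups(g, test=test)
            assert res.omnibus.pvalue < 0.05

    def test_nemenyi_detects_well_separated_groups(self):
        pmat = nemenyi_rank_all_pairs(groups_of(
            [1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]))
        assert pmat[0, 2] < 0.05
        assert np.allclose(pmat, pmat.T)
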