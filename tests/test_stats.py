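"""Oracle-based tests for the self-implemented statistical tests.

The oracles are independently coded: brute-force F statistics from the
sums-of-squares definitions, exact-fraction hypergeometric enumeration for
Fisher, plus scipy/statsmodels as cross-checks on random instances.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from embryovar import anova_oneway, bh_adjust, fisher_2x2, levene_test
from embryovar.stats import anova_many, levene_many


def brute_force_f(groups):
    """One-way F from first principles (textbook sums of squares)."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, sps.f.sf(f, df1, df2)


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by full enumeration in rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(c1, r1) + 1)
    }
    obs = pmf[a]
    cutoff = obs + obs * Fraction(1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))


class TestLevene:
    def test_identical_groups(self):
        res = levene_test([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_separated_spreads(self):
        res = levene_test([[0, 0, 0, 0], [-10, 10, -10, 10]])
        assert res.p_value < 0.01

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_anova_on_deviations_oracle(self, center):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(0, rng.uniform(0.5, 2), rng.integers(3, 10))
                      for _ in range(k)]
            centred = (
                [np.abs(g - g.mean()) for g in groups]
                if center == "mean"
                else [np.abs(g - np.median(g)) for g in groups]
            )
            f, p = brute_force_f(centred)
            res = levene_test(groups, center=center)
            assert res.statistic == pytest.approx(f, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, s, 8) for s in (1, 1, 2, 3)]
        res = levene_test(groups, center="mean")
        ref = sps.levene(*groups, center="mean")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestAnova:
    def test_identical_groups_p_one(self):
        assert anova_oneway([[1, 2, 3], [1, 2, 3]]).p_value == 1.0

    def test_separated_means(self):
        res = anova_oneway([[0.0, 0.01, -0.01], [5.0, 5.01, 4.99]])
        assert res.p_value < 1e-6

    def test_hand_computed_two_by_three(self):
        # groups (1,2,3) and (5,6,7): SSB = 24, SSW = 4, F = 24/(4/4) = 24
        res = anova_oneway([[1, 2, 3], [5, 6, 7]])
        assert res.statistic == pytest.approx(24.0)
        assert res.df == (1, 4)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 9))
                      for _ in range(rng.integers(2, 5))]
            f, p = brute_force_f(groups)
            res = anova_oneway(groups)
            assert res.statistic == pytest.approx(f, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)


class TestVectorised:
    """levene_many / anova_many agree with the scalar implementations."""

    def test_agreement_with_scalar(self):
        rng = np.random.default_rng(17)
        labels = np.repeat([0, 1, 2, 3], [5, 6, 4, 7])
        X = rng.normal(size=(30, len(labels)))
        lf, lp = levene_many(X, labels)
        af, ap = anova_many(X, labels)
        for i in range(X.shape[0]):
            groups = [X[i, labels == g] for g in range(4)]
            assert lf[i] == pytest.approx(levene_test(groups).statistic, abs=1e-10)
            assert lp[i] == pytest.approx(levene_test(groups).p_value, abs=1e-12)
            assert af[i] == pytest.approx(anova_oneway(groups).statistic, abs=1e-10)
            assert ap[i] == pytest.approx(anova_oneway(groups).p_value, abs=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_dominates_raw_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_permutation_commutes(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisher:
    def test_balanced_table(self):
        res = fisher_2x2(10, 10, 10, 10)
        assert res.odds_ratio == 1.0
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.direction == "none"

    def test_diagonal_table(self):
        res = fisher_2x2(5, 0, 0, 5)
        assert res.p_two_sided == pytest.approx(2 / 252, abs=1e-12)
        assert res.direction == "enrichment"

    def test_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(8)
        n_checked = 0
        while n_checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            res = fisher_2x2(a, b, c, d)
            assert res.p_two_sided == pytest.approx(
                fisher_enumeration(a, b, c, d), abs=1e-12
            )
            n_checked += 1

    def test_transpose_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            if a + b + c + d == 0:
                continue
            p = fisher_2x2(a, b, c, d).p_two_sided
            assert fisher_2x2(a, c, b, d).p_two_sided == pytest.approx(p, abs=1e-12)
            assert fisher_2x2(d, c, b, a).p_two_sided == pytest.approx(p, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 0, 0)
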