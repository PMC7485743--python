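"""Statistical primitives: frozen examples, enumeration oracles, invariants."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from longbat import stats


class TestSignedRank:
    @pytest.mark.parametrize(
        "diffs, alternative, expected",
        [
            ([1, 2, 3], "greater", 0.125),
            ([-1, -2, -3], "greater", 1.0),
            ([1, 2, 3], "less", 1.0),
        ],
    )
    def test_small_examples(self, diffs, alternative, expected):
        res = stats.wilcoxon_signed_rank(diffs, alternative)
        assert res.exact
        assert res.p_value == pytest.approx(expected)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            stats.wilcoxon_signed_rank([0, 0, 0], "greater")

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for n in range(1, 9):
            for _ in range(5):
                d = np.round(rng.standard_normal(n), 2)
                d[d == 0] = 0.5
                for alt in stats.ALTERNATIVES:
                    got = stats.wilcoxon_signed_rank(d, alt).p_value
                    want = helpers.signed_rank_p_enumeration(d, alt)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(15)
        got = stats.wilcoxon_signed_rank(d, "greater").p_value
        want = scipy.stats.wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert got == pytest.approx(want, rel=1e-10)

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(4)
        res = stats.wilcoxon_signed_rank(rng.standard_normal(60) + 0.5, "greater")
        assert not res.exact
        assert res.p_value < 0.05


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, alternative, expected",
        [
            ([1, 2], [3, 4], "less", 1 / 6),
            ([3, 4], [1, 2], "less", 1.0),
            ([5, 5, 5], [5, 5, 5], "two_sided", 1.0),
        ],
    )
    def test_small_examples(self, x, y, alternative, expected):
        assert stats.wilcoxon_rank_sum(x, y, alternative).p_value == pytest.approx(expected)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_rank_sum([], [1.0], "less")

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for nx in range(1, 7):
            for ny in range(1, 9 - nx):
                x = rng.standard_normal(nx)
                y = rng.standard_normal(ny)
                for alt in stats.ALTERNATIVES:
                    got = stats.wilcoxon_rank_sum(x, y, alt).p_value
                    want = helpers.rank_sum_p_enumeration(x, y, alt)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_approximation(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(30)
        y = rng.standard_normal(25) + 0.3
        got = stats.wilcoxon_rank_sum(x, y, "two_sided").p_value
        want = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert got == pytest.approx(want, rel=1e-6)


class TestFisher:
    @pytest.mark.parametrize(
        "table, alternative, expected",
        [
            ([[3, 1], [1, 3]], "greater", 17 / 70),
            ([[5, 0], [0, 5]], "greater", 1 / 252),
            ([[1, 1], [1, 1]], "two_sided", 1.0),
        ],
    )
    def test_small_examples(self, table, alternative, expected):
        assert stats.fisher_exact_2x2(table, alternative).p_value == pytest.approx(expected)

    def test_negative_cell_error(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[1, -1], [2, 3]], "greater")

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = rng.integers(0, 40, size=(2, 2))
            if t.sum() == 0:
                continue
            for alt, scipy_alt in [
                ("greater", "greater"),
                ("less", "less"),
                ("two_sided", "two-sided"),
            ]:
                got = stats.fisher_exact_2x2(t, alt).p_value
                want = scipy.stats.fisher_exact(t, alternative=scipy_alt)[1]
                assert got == pytest.approx(want, rel=1e-7)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.01, 0.04], [0.02, 0.04]),
        ],
    )
    def test_small_examples(self, p, expected):
        assert stats.bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_properties(self, p):
        q = stats.bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        # permutation equivariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = stats.bh_adjust(np.asarray(p)[perm])
        assert q_perm == pytest.approx(q[perm])
        # monotone in the raw p-values
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestKS:
    def test_examples(self):
        assert stats.ks_2samp([1, 2, 3], [1, 2, 3]).statistic == 0.0
        assert stats.ks_2samp([1, 2], [3, 4]).statistic == 1.0
        assert stats.ks_2samp([1, 3], [2, 4]).statistic == 0.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            stats.ks_2samp([], [1.0])

    def test_matches_scipy_statistic_and_kolmogorov_series(self):
        import math

        rng = np.random.default_rng(6)
        x = rng.standard_normal(80)
        y = rng.standard_normal(90) + 0.2
        got = stats.ks_2samp(x, y)
        want = scipy.stats.ks_2samp(x, y, mode="asymp")
        assert got.statistic == pytest.approx(want.statistic)
        en = math.sqrt(80 * 90 / 170)
        assert got.p_value == pytest.approx(
            scipy.special.kolmogorov(en * got.statistic), rel=1e-10
        )


class TestChi2:
    def test_examples(self):
        res = stats.chi2_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert stats.chi2_2x2([[20, 10], [10, 20]]).statistic == pytest.approx(6.6667, abs=1e-4)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            stats.chi2_2x2([[1, 0], [0, 0]])

    def test_matches_scipy_without_correction(self):
        t = [[23, 41], [17, 9]]
        got = stats.chi2_2x2(t)
        want = scipy.stats.chi2_contingency(t, correction=False)
        assert got.statistic == pytest.approx(want[0])
        assert got.p_value == pytest.approx(want[1])


class TestSpearman:
    def test_examples(self):
        assert stats.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert stats.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
        assert stats.spearman_rho([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_error(self):
        with pytest.raises(ValueError, match="constant"):
            stats.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, 40).astype(float)
        y = x + rng.integers(0, 3, 40)
        assert stats.spearman_rho(x, y) == pytest.approx(scipy.stats.spearmanr(x, y)[0])


class TestHDI:
    def test_examples(self):
        iv = stats.hdi(np.arange(1, 21) / 100, 0.95)
        assert (iv.lower, iv.upper) == (0.01, 0.19)
        iv = stats.hdi([3.0, 3.0, 3.0], 0.95)
        assert (iv.lower, iv.upper) == (3.0, 3.0)
        sample = np.random.default_rng(8).random(50)
        iv = stats.hdi(sample, 1.0)
        assert (iv.lower, iv.upper) == (sample.min(), sample.max())

    def test_empty_error(self):
        with pytest.raises(ValueError):
            stats.hdi([], 0.95)

    def test_matches_window_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 200))
            sample = rng.random(n)
            mass = float(rng.uniform(0.2, 1.0))
            iv = stats.hdi(sample, mass)
            lo, hi = helpers.hdi_window_scan(sample, mass)
            assert (iv.lower, iv.upper) == (lo, hi)


class TestTypeIError:
    """Empirical size at alpha=0.05 under continuous null data (10,000 reps)."""

    R = 10_000

    def test_signed_rank(self):
        rng = np.random.default_rng(101)
        hits = sum(
            stats.wilcoxon_signed_rank(rng.standard_normal(20), "greater").p_value <= 0.05
            for _ in range(self.R)
        )
        assert 0.04 <= hits / self.R <= 0.06

    def test_rank_sum(self):
        rng = np.random.default_rng(102)
        hits = sum(
            stats.wilcoxon_rank_sum(
                rng.standard_normal(10), rng.standard_normal(10), "two_sided"
            ).p_value
            <= 0.05
            for _ in range(self.R)
        )
        assert 0.04 <= hits / self.R <= 0.06

    def test_chi2(self):
        rng = np.random.default_rng(103)
        a = rng.binomial(200, 0.5, self.R)
        c = rng.binomial(200, 0.5, self.R)
        hits = sum(
            stats.chi2_2x2([[a[i], 200 - a[i]], [c[i], 200 - c[i]]]).p_value <= 0.05
            for i in range(self.R)
        )
        assert 0.04 <= hits / self.R <= 0.06

    def test_ks(self):
        rng = np.random.default_rng(104)
        hits = sum(
            stats.ks_2samp(rng.standard_normal(500), rng.standard_normal(500)).p_value <= 0.05
            for _ in range(self.R)
        )
        assert 0.04 <= hits / self.R <= 0.06

    def test_fisher_never_anticonservative(self):
        # discrete 2x2 tables: the exact test is conservative, never above nominal
        rng = np.random.default_rng(105)
        a = rng.binomial(30, 0.3, self.R)
        c = rng.binomial(30, 0.3, self.R)
        hits = sum(
            stats.fisher_exact_2x2([[a[i], 30 - a[i]], [c[i], 30 - c[i]]], "two_sided").p_value
            <= 0.05
            for i in range(self.R)
        )
        assert hits / self.R <= 0.055
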