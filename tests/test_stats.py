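"""Unit and property tests for the statistical primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from temark import stats


class TestPoissonPresenceThreshold:
    @pytest.mark.parametrize(
        "lam, alpha, n_tests, expected",
        [
            # P(X>=3 | 1) = 0.0803 >= 0.05 but P(X>=4 | 1) = 0.0190 < 0.05
            (1.0, 0.05, 1, 4),
            # P(X>=8 | 2) = 1.10e-3 >= 1e-3 but P(X>=9 | 2) = 2.4e-4 < 1e-3
            (2.0, 0.001, 1, 9),
        ],
    )
    def test_examples_from_tail_sums(self, lam, alpha, n_tests, expected):
        assert stats.poisson_presence_threshold(lam, alpha, n_tests) == expected

    def test_threshold_definition_holds(self):
        for lam in (0.1, 1.0, 4.5, 20.0):
            for level in (0.05, 1e-3, 1e-6):
                k = stats.poisson_presence_threshold(lam, level, 1)
                assert sps.poisson.sf(k - 1, lam) < level
                assert k == 1 or sps.poisson.sf(k - 2, lam) >= level

    def test_loose_level_gives_trivial_bound(self):
        assert stats.poisson_presence_threshold(1.0, 0.999, 1) <= 1

    def test_bonferroni_raises_threshold(self):
        k1 = stats.poisson_presence_threshold(3.0, 0.05, 1)
        k100 = stats.poisson_presence_threshold(3.0, 0.05, 100)
        assert k100 > k1

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            stats.poisson_presence_threshold(0.0, 0.05, 1)


class TestGTest:
    def test_identity_gives_zero(self):
        res = stats.g_test([10, 20, 30], [10, 20, 30])
        assert res.G == 0.0
        assert res.p == 1.0
        assert res.df == 2

    def test_two_cell_example(self):
        # 2 * (150 ln 1.5 + 850 ln(850/900)) = 24.470...
        res = stats.g_test([150, 850], [100, 900])
        assert res.G == pytest.approx(24.470, abs=1e-3)
        assert res.df == 1

    def test_zero_observed_cell_uses_zero_convention(self):
        res = stats.g_test([0, 100], [50, 50])
        assert np.isfinite(res.G) and res.G > 0

    @given(st.permutations(range(4)))
    @settings(deadline=None, max_examples=24, derandomize=True)
    def test_category_order_invariance(self, perm):
        o = np.array([12.0, 7.0, 31.0, 4.0])
        e = np.array([10.0, 10.0, 30.0, 4.0])
        base = stats.g_test(o, e).G
        p = np.array(perm)
        assert stats.g_test(o[p], e[p]).G == pytest.approx(base, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stats.g_test([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            stats.g_test([-1, 4], [1, 2])
        with pytest.raises(ValueError):
            stats.g_test([1, 2], [0, 3])
        with pytest.raises(ValueError):
            stats.g_test([10, 10], [5, 5])  # totals differ


class TestCorrelate:
    def test_monotone_series_gives_spearman_one(self):
        x = np.arange(10.0)
        y = np.exp(x)
        res = stats.correlate(x, y, method="spearman")
        assert res.coefficient == 1.0
        assert res.p == 0.0

    def test_t_statistic_formula(self):
        # engineered r = 0.8 check via direct formula: t = r sqrt((n-2)/(1-r^2))
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            res = stats.correlate(x, y, method="pearson")
            r = res.coefficient
            assert res.t == pytest.approx(r * np.sqrt(8 / (1 - r * r)), rel=1e-12)
        assert 0.8 * np.sqrt(8 / (1 - 0.64)) == pytest.approx(3.771, abs=1e-3)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = stats.correlate(x, y, method="spearman")
        for f in (np.exp, lambda v: v**3, lambda v: 10 * v - 2):
            res = stats.correlate(f(x), y, method="spearman")
            assert res.coefficient == pytest.approx(base.coefficient, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 2.0, 3.0, 4.0]
        res = stats.correlate(x, y, method="spearman")
        ref = sps.spearmanr(x, y)
        assert res.coefficient == pytest.approx(ref.statistic, abs=1e-12)

    def test_auto_picks_pearson_for_normal_spearman_for_skewed(self):
        rng = np.random.default_rng(3)
        normal = rng.normal(size=300)
        skewed = rng.exponential(size=300)
        assert stats.correlate(normal, rng.normal(size=300), method="auto").method == "pearson"
        assert stats.correlate(skewed, rng.normal(size=300), method="auto").method == "spearman"

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            stats.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = stats.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, size=25)
        t1, p1 = stats.two_sample_t(a, b)
        t2, p2 = stats.two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_matches_closed_form(self):
        # pooled t at alpha=0.05 on N(0,1) vs N(1,1), n=50 each: compare the
        # simulated rejection rate against the noncentral-t power oracle.
        rng = np.random.default_rng(123)
        n, reps = 50, 1000
        rejections = 0
        for _ in range(reps):
            _, p = stats.two_sample_t(rng.normal(size=n), rng.normal(1.0, 1.0, size=n))
            rejections += p < 0.05
        df = 2 * n - 2
        nc = 1.0 / np.sqrt(2 / n)
        crit = sps.t.ppf(0.975, df)
        power = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
        observed = rejections / reps
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(observed - power) < 4 * se

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([2.0, 2.0], [2.0, 2.0])


class TestNormalityCheck:
    def test_exact_normal_quantiles_pass(self):
        x = sps.norm.ppf((np.arange(100) + 0.5) / 100)
        assert stats.normality_check(x).is_normal

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(42).exponential(scale=1.0, size=200)
        assert not stats.normality_check(x).is_normal

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=150)
        base = stats.normality_check(x)
        shifted = stats.normality_check(5.0 - 3.0 * x)
        assert base.is_normal == shifted.is_normal
        assert base.r == pytest.approx(shifted.r, abs=1e-9)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            stats.normality_check(np.arange(5.0))


class TestBonferroni:
    def test_values(self):
        assert stats.bonferroni(0.05, 1) == 0.05
        assert stats.bonferroni(0.05, 228) == pytest.approx(2.19e-4, rel=1e-2)

    @given(st.integers(min_value=1, max_value=10_000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_nonincreasing(self, n):
        assert stats.bonferroni(0.05, n + 1) <= stats.bonferroni(0.05, n)
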