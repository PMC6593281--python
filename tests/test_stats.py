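"""Statistical battery: Welch t, Mann-Whitney, chi-square, adjusted comparison,
Bonferroni, partial correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from topofc import (
    SummaryStat,
    adjusted_group_compare,
    bonferroni,
    chi_square_counts,
    mann_whitney,
    partial_correlation,
    welch_t,
    welch_t_from_summary,
)
from topofc.stats import summarize


class TestWelch:
    def test_identical_summaries_give_p_one(self):
        a = SummaryStat(mean=5.0, sem=0.5, n=30)
        res = welch_t_from_summary(a, a)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_on_raw_data(self, rng):
        for _ in range(10):
            a = rng.standard_normal(25) * 2 + 1
            b = rng.standard_normal(31) * 3
            res = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    @given(
        arrays(float, 12, elements=st.floats(-50, 50)),
        arrays(float, 9, elements=st.floats(-50, 50)),
    )
    def test_summary_and_raw_forms_identical(self, a, b):
        if np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
            return
        r1 = welch_t(a, b)
        r2 = welch_t_from_summary(summarize(a), summarize(b))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal(20) + 1, rng.standard_normal(20)
        r1, r2 = welch_t(a, b), welch_t(1000 * a, 1000 * b)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_zero_variance_degenerate(self):
        assert welch_t([1.0, 1.0], [1.0, 1.0]).p == 1.0
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(77)
        rejections = sum(
            welch_t(rng.standard_normal(30), rng.standard_normal(30)).p < 0.05
            for _ in range(1000)
        )
        assert 0.035 <= rejections / 1000 <= 0.065


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert min(res.statistic, 9 - res.statistic) == 0.0

    def test_identical_groups(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p > 0.99

    def test_exact_small_sample_matches_enumeration(self, rng):
        """For n=4 vs 4 without ties the exact p equals the fraction of the 70
        rank splits with a U at least as extreme."""
        a = rng.standard_normal(4)
        b = rng.standard_normal(4) + 0.5
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        us = []
        for combo in itertools.combinations(range(8), 4):
            us.append(ranks[list(combo)].sum() - 4 * 5 / 2)
        us = np.array(us)
        p_enum = np.mean(np.minimum(us, 16 - us) <= min(u_obs, 16 - u_obs))
        assert res.p == pytest.approx(p_enum, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_equal_proportions(self):
        res = chi_square_counts([[18, 12], [18, 12]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_hand_computed(self):
        res = chi_square_counts([[30, 0], [0, 30]])
        assert res.statistic == pytest.approx(60.0)
        assert res.p < 1e-10

    def test_row_swap_symmetry(self):
        t = [[20, 10], [14, 16]]
        assert chi_square_counts(t).statistic == pytest.approx(
            chi_square_counts(t[::-1]).statistic
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_counts([[0, 0], [5, 5]])


class TestAdjustedCompare:
    def test_no_covariates_reduces_to_pooled_t(self, rng):
        y = np.concatenate([rng.standard_normal(15) + 0.5, rng.standard_normal(15)])
        g = ["a"] * 15 + ["b"] * 15
        res = adjusted_group_compare(y, g, None)
        ref = sps.ttest_ind(y[15:], y[:15], equal_var=True)
        assert abs(res.statistic) == pytest.approx(abs(ref.statistic))
        assert res.p == pytest.approx(ref.pvalue)

    def test_orthogonal_covariate_leaves_effect_estimate(self, rng):
        n = 40
        g = ["a"] * 20 + ["b"] * 20
        cov = np.tile([1.0, -1.0], 20)  # balanced within groups -> orthogonal
        y = np.concatenate([np.zeros(20), np.ones(20)]) + 0.3 * cov + rng.standard_normal(n) * 0.1
        res = adjusted_group_compare(y, g, pd.DataFrame({"c": cov}))
        import statsmodels.api as sm

        ind = np.array([0.0] * 20 + [1.0] * 20)
        fit = sm.OLS(y, np.column_stack([np.ones(n), ind])).fit()
        assert res.statistic * fit.params[1] > 0  # same direction
        # coefficient equals unadjusted mean difference when covariate orthogonal
        fit_adj = sm.OLS(y, np.column_stack([np.ones(n), ind, cov])).fit()
        assert fit_adj.params[1] == pytest.approx(y[20:].mean() - y[:20].mean(), abs=1e-10)

    def test_type_one_error_with_active_covariate(self):
        rng = np.random.default_rng(123)
        rej = 0
        for _ in range(500):
            cov = rng.standard_normal(40)
            y = 2.0 * cov + rng.standard_normal(40)
            g = ["a"] * 20 + ["b"] * 20
            res = adjusted_group_compare(y, g, pd.DataFrame({"c": cov}))
            rej += res.p < 0.05
        assert 0.02 <= rej / 500 <= 0.08

    def test_rank_deficiency_and_small_group_errors(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="2 groups"):
            adjusted_group_compare(y, ["a"] * 10, None)
        with pytest.raises(ValueError, match="at least 2"):
            adjusted_group_compare(y, ["a"] * 9 + ["b"], None)


class TestBonferroni:
    def test_single_test_reduces_to_raw_threshold(self):
        adj, rej = bonferroni([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_example_family_of_five(self):
        adj, rej = bonferroni([0.01, 0.5, 0.02, 0.009, 0.2], alpha=0.05)
        assert adj[0] == pytest.approx(0.05)
        assert rej[0] and rej[3]
        assert not rej[1] and not rej[2]

    @given(arrays(float, 8, elements=st.floats(0, 1)))
    def test_adjusted_never_below_raw(self, p):
        adj, _ = bonferroni(p)
        assert np.all(adj >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        r, p = partial_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_perfect_dependence(self, rng):
        x = rng.standard_normal(20)
        r, p = partial_correlation(x, x.copy())
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(40)
        z = rng.standard_normal((40, 2))
        y = 0.4 * x + 0.7 * z[:, 0] + rng.standard_normal(40)
        r, p = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_confound_removed(self, rng):
        z = rng.standard_normal(200)
        x = z + 0.1 * rng.standard_normal(200)
        y = -z + 0.1 * rng.standard_normal(200)
        r_raw, _ = partial_correlation(x, y)
        r_adj, _ = partial_correlation(x, y, z[:, None])
        assert r_raw < -0.9
        assert abs(r_adj) < 0.3

    def test_insufficient_df(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation(np.ones(4), np.ones(4), np.ones((4, 2)))
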