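import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anacap import bonferroni, paired_t, rm_anova_oneway, rm_anova_twoway


def brute_force_oneway(X):
    """SS partition computed straight from the definitions with loops."""
    n, k = X.shape
    g = X.mean()
    ss_treat = sum(n * (X[:, j].mean() - g) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i, :].mean() - g) ** 2 for i in range(n))
    ss_total = sum((X[i, j] - g) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_treat - ss_subj
    F = (ss_treat / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return ss_treat, ss_err, F


def brute_force_twoway(Y):
    """Fully-within two-way SS partition from definitions (loops)."""
    n, a, b = Y.shape
    g = Y.mean()
    A = [Y[:, i, :].mean() for i in range(a)]
    B = [Y[:, :, j].mean() for j in range(b)]
    S = [Y[s].mean() for s in range(n)]
    ss_a = n * b * sum((Ai - g) ** 2 for Ai in A)
    ss_b = n * a * sum((Bj - g) ** 2 for Bj in B)
    ss_ab = n * sum(
        (Y[:, i, j].mean() - A[i] - B[j] + g) ** 2 for i in range(a) for j in range(b)
    )
    ss_sa = b * sum(
        (Y[s, i, :].mean() - S[s] - A[i] + g) ** 2 for s in range(n) for i in range(a)
    )
    ss_sb = a * sum(
        (Y[s, :, j].mean() - S[s] - B[j] + g) ** 2 for s in range(n) for j in range(b)
    )
    return ss_a, ss_b, ss_ab, ss_sa, ss_sb


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_computed_t(self):
        # differences {1,2,3,4}: mean 2.5, sd 1.2910 → t = 2.5/(1.2910/2)
        x = np.array([2.0, 4.0, 6.0, 8.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(3.873, abs=0.001)
        assert res.df[0] == 3

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.3, 1, 12)
        from scipy import stats as sps

        ref = sps.ttest_rel(x, y)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_false_positive_rate_near_alpha_under_generator_null(self):
        """Paired comparisons of two same-condition noisy bouts reject at
        ~5% across 500 simulated studies of 9 participants."""
        from anacap import PLACEBO, make_participant, mean_last_window, simulate_constant_load

        rejections = 0
        n_studies = 500
        rng = np.random.default_rng(123)
        truths = [make_participant(s) for s in range(9)]
        for study in range(n_studies):
            x, y = [], []
            for pid, truth in enumerate(truths):
                power = 0.8 * truth.get_power
                seeds = rng.integers(0, 2**31, size=2)
                for out, seed in ((x, seeds[0]), (y, seeds[1])):
                    tr = simulate_constant_load(truth, PLACEBO, power, max_duration=120.0, seed=int(seed))
                    out.append(mean_last_window(tr.breaths, 30.0))
            if paired_t(x, y).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_studies <= 0.08


class TestOneWayRMAnova:
    def test_identical_columns_give_zero_f(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        res = rm_anova_oneway(X)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_brute_force_partition(self):
        X = np.array([[3.0, 4.0, 6.0], [5.0, 6.0, 7.0], [2.0, 2.0, 5.0], [4.0, 7.0, 8.0]])
        res = rm_anova_oneway(X)
        ss_treat, ss_err, F = brute_force_oneway(X)
        assert res.effects["treatment"]["ss"] == pytest.approx(ss_treat, abs=1e-10)
        assert res.effects["treatment"]["ss_error"] == pytest.approx(ss_err, abs=1e-10)
        assert res.statistic == pytest.approx(F, abs=1e-10)
        assert res.df == (2.0, 6.0)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.ones((4, 1)))

    def test_missing_cells_rejected(self):
        X = np.ones((3, 3))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_oneway(X)

    def test_posthoc_bonferroni_pairs(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (6, 3))
        X[:, 2] += 3.0
        res = rm_anova_oneway(X, posthoc=True)
        assert len(res.posthoc) == 3
        assert all(0 <= p <= 1 for _, p in res.posthoc)


class TestTwoWayRMAnova:
    def test_additive_data_has_zero_interaction(self):
        n, a, b = 4, 2, 3
        subj = np.arange(n)[:, None, None] * 1.0
        fa = np.array([0.0, 2.0])[None, :, None]
        fb = np.array([0.0, 1.0, 3.0])[None, None, :]
        Y = subj + fa + fb
        res = rm_anova_twoway(Y)
        assert res.effects["interaction"]["F"] == 0.0
        assert res.effects["factor_a"]["p"] < 0.05 or res.effects["factor_a"]["F"] == float("inf")

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, (3, 2, 2))
        res = rm_anova_twoway(Y)
        ss_a, ss_b, ss_ab, ss_sa, ss_sb = brute_force_twoway(Y)
        assert res.effects["factor_a"]["ss"] == pytest.approx(ss_a, abs=1e-10)
        assert res.effects["factor_b"]["ss"] == pytest.approx(ss_b, abs=1e-10)
        assert res.effects["interaction"]["ss"] == pytest.approx(ss_ab, abs=1e-10)
        assert res.effects["factor_a"]["ss_error"] == pytest.approx(ss_sa, abs=1e-10)
        assert res.effects["factor_b"]["ss_error"] == pytest.approx(ss_sb, abs=1e-10)

    def test_missing_cell_rejected(self):
        Y = np.ones((3, 2, 2))
        Y[0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_twoway(Y)


class TestBonferroni:
    def test_basic_adjustment(self):
        assert bonferroni([0.01, 0.04]) == [0.02, 0.08]

    def test_capped_at_one(self):
        assert bonferroni([0.9], m=3) == [1.0]

    def test_empty(self):
        assert bonferroni([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), max_size=8))
    def test_adjusted_never_below_raw_and_in_unit_interval(self, ps):
        adj = bonferroni(ps)
        assert all(0 <= q <= 1 for q in adj)
        assert all(q >= p - 1e-15 for p, q in zip(ps, adj))
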