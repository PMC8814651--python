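"""Statistics checked against independent oracles: hand formulas evaluated
with plain numpy, and pingouin for alpha/ICC."""

import math

import numpy as np
import pandas as pd
import pytest

from foodlit.errors import ComputationError
from foodlit.psychometrics import test_retest as run_test_retest
from foodlit.psychometrics import (
    construct_validity_flag,
    cronbach_alpha,
    icc_agreement,
    independent_t_test,
    pearson,
)


def pearson_oracle(x, y):
    """Brute-force product-moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb)))


class TestPearson:
    def test_identity(self):
        assert pearson([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)

    def test_negation(self):
        assert pearson([1, 2, 3, 4], [-1, -2, -3, -4]).r == pytest.approx(-1.0)

    def test_against_oracle(self):
        x, y = [1, 2, 3, 4], [1, 2, 3, 5]
        assert pearson(x, y).r == pytest.approx(pearson_oracle(x, y), abs=1e-10)

    def test_p_value_from_t_transform(self):
        from scipy import stats

        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.1, 1.9, 3.4, 3.9, 5.2]
        res = pearson(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_symmetry(self):
        x, y = [1, 5, 2, 8], [2, 1, 7, 3]
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)

    def test_affine_invariance(self):
        x, y = np.array([1.0, 5, 2, 8]), np.array([2.0, 1, 7, 3])
        assert pearson(3 * x + 1, y).r == pytest.approx(pearson(x, y).r)

    def test_constant_series_errors(self):
        with pytest.raises(ComputationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ComputationError):
            pearson([1, 2], [3, 4])

    def test_pairwise_deletion(self):
        r = pearson([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert r.n == 3


class TestConstructValidityFlag:
    @pytest.mark.parametrize(
        "r,flag",
        [
            (0.536, "good"),
            (0.685, "good"),
            (0.95, "too_high"),
            (0.9, "too_high"),
            (0.4, "too_low"),
            (0.1, "too_low"),
            (-0.5, "too_low"),
        ],
    )
    def test_bands(self, r, flag):
        assert construct_validity_flag(r) == flag

    def test_out_of_range(self):
        with pytest.raises(ComputationError):
            construct_validity_flag(1.5)


class TestCronbachAlpha:
    def test_parallel_duplicate_items(self):
        m = np.array([[1, 1], [2, 2], [3, 3], [5, 5]], dtype=float)
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_toy_matrix_against_pingouin(self):
        m = np.array(
            [[2, 3, 4], [4, 4, 5], [1, 2, 2], [3, 3, 3]], dtype=float
        )
        import pingouin as pg

        expected = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert cronbach_alpha(m) == pytest.approx(expected, abs=1e-10)

    def test_toy_matrix_against_hand_formula(self):
        m = np.array([[2, 3, 4], [4, 4, 5], [1, 2, 2], [3, 3, 3]], dtype=float)
        k = 3
        expected = k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / m.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(m) == pytest.approx(expected, abs=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1234)
        m = rng.normal(size=(4000, 4))
        assert abs(cronbach_alpha(m)) < 0.1

    def test_compound_symmetry_closed_form(self):
        # items = trait + iid noise -> alpha = k*cbar / (1 + (k-1)*cbar)
        rng = np.random.default_rng(7)
        n, k = 50_000, 4
        trait = rng.normal(size=n)
        m = trait[:, None] + rng.normal(scale=1.0, size=(n, k))
        cbar = 0.5  # var(trait) / (var(trait) + var(noise))
        closed = k * cbar / (1 + (k - 1) * cbar)
        assert cronbach_alpha(m) == pytest.approx(closed, abs=0.02)

    def test_zero_total_variance_errors(self):
        with pytest.raises(ComputationError):
            cronbach_alpha(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_degenerate_shapes_error(self):
        with pytest.raises(ComputationError):
            cronbach_alpha(np.array([[1.0], [2.0]]))
        with pytest.raises(ComputationError):
            cronbach_alpha(np.array([[1.0, 2.0]]))


class TestICC:
    def icc_oracle(self, x, y):
        """Two-way ANOVA mean squares by explicit summation."""
        data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    def test_against_oracle(self):
        x = [8.0, 6.5, 4.0, 9.0, 5.5]
        y = [7.0, 6.0, 5.0, 8.5, 6.0]
        assert icc_agreement(x, y) == pytest.approx(self.icc_oracle(x, y), abs=1e-10)

    def test_against_pingouin(self):
        import pingouin as pg

        x = [8.0, 6.5, 4.0, 9.0, 5.5]
        y = [7.0, 6.0, 5.0, 8.5, 6.0]
        long = pd.DataFrame(
            {
                "target": list(range(5)) * 2,
                "rater": ["t1"] * 5 + ["t2"] * 5,
                "score": x + y,
            }
        )
        table = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        table = table.set_index("Type")
        # two-way absolute-agreement single measures; label varies by version
        label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        expected = float(table.loc[label, "ICC"])
        assert icc_agreement(x, y) == pytest.approx(expected, abs=1e-10)

    def test_exact_agreement(self):
        assert icc_agreement([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)


class TestTestRetest:
    def test_identical_waves(self):
        res = run_test_retest([60.0, 70.0, 80.0], [60.0, 70.0, 80.0])
        assert res.pearson_r == 1.0
        assert res.icc == pytest.approx(1.0)
        assert res.reliable and res.reliable_icc

    def test_constant_shift_penalized_by_icc_only(self):
        t1 = np.array([60.0, 65.0, 70.0, 80.0, 75.0])
        res = run_test_retest(t1, t1 + 10.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.icc < 1.0

    def test_icc_at_most_pearson_for_shifted_replicates(self):
        rng = np.random.default_rng(5)
        t1 = rng.normal(70, 7, 200)
        t2 = t1 + 5 + rng.normal(0, 2, 200)
        res = run_test_retest(t1, t2)
        assert res.icc <= res.pearson_r + 1e-9

    def test_unpaired_errors(self):
        with pytest.raises(ComputationError):
            run_test_retest([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_additive_noise_model_recovery(self):
        # closed-form reliability of scores = trait + noise on both waves
        rng = np.random.default_rng(99)
        n = 1000
        trait = rng.normal(0, 1, n)
        sd = 0.6
        t1 = trait + rng.normal(0, sd, n)
        t2 = trait + rng.normal(0, sd, n)
        expected = 1.0 / (1.0 + sd**2)
        res = run_test_retest(t1, t2)
        assert res.pearson_r == pytest.approx(expected, abs=0.1)


class TestTTest:
    def test_identical_groups(self):
        res = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_large_separation_significant(self):
        res = independent_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.05
        assert res.significant

    def test_against_pooled_oracle(self):
        a = [68.0, 71.0, 69.0, 73.0]
        b = [70.0, 74.0, 72.0]
        res = independent_t_test(a, b)
        assert res.t == pytest.approx(pooled_t_oracle(a, b), abs=1e-10)

    def test_welch_flag_changes_statistic(self):
        a = [1.0, 2.0, 3.0, 4.0, 100.0]
        b = [2.0, 2.1, 2.2]
        pooled = independent_t_test(a, b)
        welch = independent_t_test(a, b, welch=True)
        assert pooled.t != pytest.approx(welch.t)

    def test_small_group_errors(self):
        with pytest.raises(ComputationError):
            independent_t_test([1.0], [1.0, 2.0])
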