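import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from gradmap import bonferroni, demographics_table, design_matrix, hotelling_group_test, spearman_with_ci
from gradmap.group_stats import hotelling_batch, sex_counts_chi2, univariate_group_test


def two_group_design(n1, n2):
    group = np.r_[np.ones(n1), np.zeros(n2)]
    return np.column_stack([np.ones(n1 + n2), group])


class TestHotelling:
    def test_identical_group_values_give_zero_statistic(self, rng):
        y_half = rng.standard_normal((15, 2))
        y = np.vstack([y_half, y_half])
        x = two_group_design(15, 15)
        res = hotelling_group_test(y, x)
        assert res.t2 == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_matches_classical_two_sample_formula(self, rng):
        n1, n2 = 18, 14
        y = np.vstack([rng.standard_normal((n1, 2)) + [0.5, 0.0], rng.standard_normal((n2, 2))])
        x = two_group_design(n1, n2)
        res = hotelling_group_test(y, x)
        d = y[:n1].mean(axis=0) - y[n1:].mean(axis=0)
        s_pooled = (
            np.cov(y[:n1].T) * (n1 - 1) + np.cov(y[n1:].T) * (n2 - 1)
        ) / (n1 + n2 - 2)
        t2_classic = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(s_pooled, d)
        assert res.t2 == pytest.approx(t2_classic, abs=1e-10)

    def test_single_response_reduces_to_squared_t(self, rng):
        n = 40
        x = np.column_stack([
            np.ones(n), rng.integers(0, 2, n).astype(float),
            rng.standard_normal(n), rng.standard_normal(n),
        ])
        y = rng.standard_normal(n) + 0.4 * x[:, 1]
        res = hotelling_group_test(y[:, None], x)
        fit = sm.OLS(y, x).fit()
        assert res.t2 == pytest.approx(fit.tvalues[1] ** 2, abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_batch_agrees_with_single_tests(self, rng):
        n, b = 30, 12
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float), rng.standard_normal(n)])
        y = rng.standard_normal((n, b, 2))
        t2, pvals = hotelling_batch(y, x)
        for j in range(b):
            res = hotelling_group_test(y[:, j, :], x)
            assert t2[j] == pytest.approx(res.t2, abs=1e-10)
            assert pvals[j] == pytest.approx(res.p, abs=1e-10)

    def test_degenerate_responses_rejected(self, rng):
        n = 20
        x = two_group_design(10, 10)
        y1 = rng.standard_normal(n)
        with pytest.raises(ValueError, match="singular"):
            hotelling_group_test(np.column_stack([y1, y1]), x)


class TestUnivariate:
    def test_reduces_to_plain_two_sample_t(self, rng):
        n1, n2 = 16, 20
        y = np.r_[rng.standard_normal(n1) + 0.8, rng.standard_normal(n2)]
        x = pd.DataFrame(two_group_design(n1, n2), columns=["intercept", "group"])
        _, tstat, pval = univariate_group_test(y, x)
        t_ref, p_ref = scipy.stats.ttest_ind(y[:n1], y[n1:], equal_var=True)
        assert tstat == pytest.approx(t_ref, abs=1e-10)
        assert pval == pytest.approx(p_ref, abs=1e-10)


class TestSpearman:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.arange(10.0)
        res = spearman_with_ci(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_rank_formula_example(self):
        res = spearman_with_ci(np.array([1, 2, 3, 4, 5.0]), np.array([3, 1, 2, 5, 4.0]))
        # sum d^2 = 4+1+1+1+1 = 8 -> rho = 1 - 6*8/(5*24) = 0.6
        assert res.rho == pytest.approx(0.6, abs=1e-12)

    def test_fisher_ci_matches_published_interval(self):
        # rho = 0.30 at n = 116 -> 95% CI [0.12, 0.46] at two decimals
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.standard_normal(116)
            y = 0.3 * x + rng.standard_normal(116)
            res = spearman_with_ci(x, y)
            lo = np.tanh(np.arctanh(res.rho) - 1.96 / np.sqrt(113))
            hi = np.tanh(np.arctanh(res.rho) + 1.96 / np.sqrt(113))
            assert res.ci95 == pytest.approx((lo, hi), abs=1e-12)
        halfwidth = 1.96 / np.sqrt(116 - 3)
        lo, hi = np.tanh(np.arctanh(0.30) - halfwidth), np.tanh(np.arctanh(0.30) + halfwidth)
        assert round(lo, 2) == 0.12 and round(hi, 2) == 0.46

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1, 2, 3, 4, 5, np.nan, 7.0])
        y = np.array([1, 2, 3, 4, 5, 6, np.nan])
        res = spearman_with_ci(x, y)
        assert res.n == 5
        assert res.rho == pytest.approx(1.0)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            spearman_with_ci(np.arange(4.0), np.arange(4.0))


class TestDemographics:
    def _manifest(self, rng, n1=20, n2=20):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["MS"] * n1 + ["HC"] * n2,
            "age": rng.normal(38, 10, n1 + n2),
            "sex": rng.choice(["M", "F"], n1 + n2),
            "mean_fd": rng.uniform(0.05, 0.2, n1 + n2),
        })

    def test_published_sex_counts_give_chi2_2p4(self):
        chi2, p = sex_counts_chi2(np.array([[38, 84], [41, 56]]))
        assert round(chi2, 1) == 2.4
        assert p > 0.05

    def test_identical_groups_give_null_statistics(self):
        chi2, p = sex_counts_chi2(np.array([[10, 20], [10, 20]]))
        assert chi2 == 0.0 and p == 1.0

    def test_t_matches_pooled_variance_formula(self, rng):
        manifest = self._manifest(rng)
        table = demographics_table(manifest).set_index("variable")
        a = manifest[manifest.group == "MS"]["age"].to_numpy()
        b = manifest[manifest.group == "HC"]["age"].to_numpy()
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
        t_expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert table.loc["age", "statistic"] == pytest.approx(t_expected, abs=1e-12)


class TestDesignAndBonferroni:
    def test_group_indicator_marks_patients(self, rng):
        manifest = pd.DataFrame({
            "subject_id": list("abcdef"), "group": ["HC", "MS", "HC", "MS", "HC", "MS"],
            "age": [30.0, 40.0, 50.0, 35.0, 45.0, 55.0], "sex": ["F", "M", "M", "F", "M", "M"],
            "mean_fd": [0.1, 0.2, 0.15, 0.12, 0.18, 0.09],
        })
        x = design_matrix(manifest, "MS")
        assert x["group"].tolist() == [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        assert x["sex"].tolist() == [0.0, 1.0, 1.0, 0.0, 1.0, 1.0]  # first-appearance coding

    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 5, 0.05), (0.4, 5, 1.0), (0.73, 1, 0.73),
    ])
    def test_bonferroni_adjustment(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)
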