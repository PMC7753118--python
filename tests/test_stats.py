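"""Analyte QC, group comparisons, correlation and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cytomet import (
    AnalytePanel,
    ancova_group_effect,
    chi_square_2x2,
    fdr_adjust,
    nd_exclusion,
    pearson_r,
    pooled_t,
    pooled_t_vectors,
)


def _panel(nd_counts: dict, n_subjects: int = 63) -> AnalytePanel:
    """Panel with a given number of non-detected entries per analyte."""
    rng = np.random.default_rng(0)
    names = list(nd_counts)
    idx = [f"s{i}" for i in range(n_subjects)]
    values = pd.DataFrame(
        rng.lognormal(1.0, 0.5, size=(n_subjects, len(names))),
        index=idx, columns=names,
    )
    mask = pd.DataFrame(False, index=idx, columns=names)
    for a, k in nd_counts.items():
        mask.iloc[:k, mask.columns.get_loc(a)] = True
    values = values.mask(mask)
    lod = pd.Series(0.5, index=names)
    return AnalytePanel(values=values, nd_mask=mask, lod=lod)


class TestNdExclusion:
    def test_just_above_threshold_excluded(self):
        # 13/63 = 20.6% > 20% -> excluded; 12/63 = 19.0% -> retained
        panel = nd_exclusion(_panel({"A": 13, "B": 12}))
        assert not panel.retained["A"]
        assert panel.retained["B"]

    def test_named_foursome_excluded(self):
        counts = {a: 2 for a in ["IL-1b", "IL-6", "TNF-a", "CCL5"]}
        counts |= {a: 20 for a in ["IL-10", "IL-15", "GM-CSF", "VEGF"]}
        panel = nd_exclusion(_panel(counts))
        excluded = [a for a in panel.analyte_names if not panel.retained[a]]
        assert sorted(excluded) == sorted(["IL-10", "IL-15", "GM-CSF", "VEGF"])

    def test_imputation_at_half_lod(self):
        panel = nd_exclusion(_panel({"A": 5}))
        imputed = panel.values.iloc[:5, 0]
        assert np.allclose(imputed, 0.25)  # LOD 0.5 / 2
        # excluded analytes keep their NaNs
        panel2 = nd_exclusion(_panel({"A": 30}))
        assert panel2.values["A"].isna().sum() == 30

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            nd_exclusion(_panel({"A": 0}), threshold=1.5)


class TestPooledT:
    @pytest.mark.parametrize(
        "label, m1, s1, m2, s2, printed",
        [
            ("NAA", 6.62, 0.43, 7.14, 0.54, 5.67),
            ("GSH", 1.70, 0.26, 1.54, 0.16, 3.77),
        ],
    )
    def test_worked_cohort_rows(self, label, m1, s1, m2, s2, printed):
        res = pooled_t(m1, s1, 63, m2, s2, 49, label=label)
        assert abs(res.statistic) == pytest.approx(printed, rel=0.02)
        assert res.df == 110

    def test_identical_groups(self):
        res = pooled_t(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_vectors_match_summaries(self, rng):
        x1 = rng.normal(3, 1, 40)
        x2 = rng.normal(2.5, 1.2, 30)
        r1 = pooled_t_vectors(x1, x2)
        r2 = pooled_t(x1.mean(), x1.std(ddof=1), 40, x2.mean(), x2.std(ddof=1), 30)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)

    def test_against_scipy(self, rng):
        x1 = rng.normal(size=25)
        x2 = rng.normal(size=31)
        res = pooled_t_vectors(x1, x2)
        t, p = sps.ttest_ind(x1, x2, equal_var=True)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pooled_t(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            pooled_t(1.0, 0.0, 10, 2.0, 1.0, 10)


class TestChiSquare:
    def test_worked_sex_table(self):
        res = chi_square_2x2(17, 46, 28, 21)
        assert res.statistic == pytest.approx(10.43, abs=0.005)
        assert res.df == 1
        assert res.p == pytest.approx(0.001, abs=5e-4)

    @pytest.mark.parametrize("table", [(10, 20, 30, 60), (5, 5, 5, 5)])
    def test_proportional_tables_give_zero(self, table):
        assert chi_square_2x2(*table).statistic == pytest.approx(0.0, abs=1e-12)

    def test_swap_invariance(self):
        a = chi_square_2x2(17, 46, 28, 21).statistic
        assert chi_square_2x2(28, 21, 17, 46).statistic == pytest.approx(a)
        assert chi_square_2x2(46, 17, 21, 28).statistic == pytest.approx(a)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


# worked ANCOVA dataset, n=8: outcome, group, one covariate
ANCOVA_Y = np.array([3.1, 4.2, 2.8, 5.0, 6.1, 5.5, 6.8, 7.2])
ANCOVA_G = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
ANCOVA_C = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 1.8, 3.2, 4.0])


class TestAncova:
    def test_against_normal_equations_oracle(self):
        res = ancova_group_effect(ANCOVA_Y, ANCOVA_G, pd.DataFrame({"c": ANCOVA_C}))
        # brute-force OLS via normal equations
        X = np.column_stack([np.ones(8), (ANCOVA_G == "b").astype(float), ANCOVA_C])
        beta = np.linalg.solve(X.T @ X, X.T @ ANCOVA_Y)
        resid = ANCOVA_Y - X @ beta
        sigma2 = resid @ resid / (8 - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        F = beta[1] ** 2 / cov[1, 1]
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.p == pytest.approx(sps.f.sf(F, 1, 5), abs=1e-10)

    def test_null_F_mean_is_one(self):
        rng = np.random.default_rng(7)
        group = np.array(["a"] * 63 + ["b"] * 49)
        cov = pd.DataFrame({"age": rng.normal(40, 10, 112),
                            "sex": rng.integers(0, 2, 112).astype(float)})
        stats = [
            ancova_group_effect(rng.normal(size=112), group, cov).statistic
            for _ in range(1000)
        ]
        # E[F(1, 108)] = 108/106 ~= 1.019; MC sd of the mean ~= 0.045
        assert np.mean(stats) == pytest.approx(108 / 106, abs=0.15)

    def test_perfect_group_separation(self):
        rng = np.random.default_rng(1)
        group = np.array(["a"] * 30 + ["b"] * 30)
        cov = pd.DataFrame({"z": rng.normal(size=60)})
        y = (group == "b").astype(float)
        res = ancova_group_effect(y + rng.normal(0, 1e-8, 60), group, cov)
        assert res.statistic > 1e6
        assert res.p < 1e-12

    def test_equals_squared_t_without_covariates(self, rng):
        y = rng.normal(size=40)
        group = np.array(["a"] * 22 + ["b"] * 18)
        res_f = ancova_group_effect(y, group, None)
        res_t = pooled_t_vectors(y[:22], y[22:])
        assert res_f.statistic == pytest.approx(res_t.statistic**2, abs=1e-8)

    def test_rank_deficiency_reported(self):
        cov = pd.DataFrame({"c1": ANCOVA_C, "c2": 2 * ANCOVA_C})
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(ANCOVA_Y, ANCOVA_G, cov)


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x).statistic == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3).statistic == pytest.approx(-1.0)

    def test_against_covariance_oracle(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert pearson_r(x, y).statistic == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestFdr:
    def test_hand_computed_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        # BH step-up: q_(i) = min over j>=i of p_(j) * m / j = 0.04 for all
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_against_step_up_oracle(self, rng):
        p = rng.uniform(size=25)
        # independent implementation of BH step-up
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(fdr_adjust(p), oracle, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])
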