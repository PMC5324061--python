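"""Discretization, HWE, correlation and baseline-comparison checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bnepi.prep import (baseline_comparison, bonferroni_threshold,
                        collapse_rare_genotypes,
                        discretize_by_control_quantiles, hwe_test,
                        spearman_matrix)


class TestDiscretize:
    def test_controls_1_to_12_split_into_equal_quartiles(self):
        values = np.arange(1, 13, dtype=float)
        cat, cuts = discretize_by_control_quantiles(values, np.ones(12, bool), 4)
        # type-7 quantiles of 1..12 at 25/50/75%
        assert np.allclose(cuts, [3.75, 6.5, 9.25])
        assert list(np.bincount(cat.codes)) == [3, 3, 3, 3]

    def test_cases_binned_by_control_cutoffs(self):
        # controls span 0..100, cases concentrated high: the case
        # distribution must not move the cut-offs
        values = np.concatenate([np.linspace(0, 100, 60), np.full(30, 99.0)])
        control = np.r_[np.ones(60, bool), np.zeros(30, bool)]
        cat, cuts = discretize_by_control_quantiles(values, control, 4)
        assert np.allclose(cuts, np.quantile(values[:60], [0.25, 0.5, 0.75]))
        assert (cat.codes[60:] == 3).all()

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            discretize_by_control_quantiles(np.ones(30), np.ones(30, bool), 4)

    def test_tertile_interval_labels(self):
        # engineered so the control tertile cut-offs are exactly 9.0 / 15.3
        controls = np.array([1.0, 5.0, 9.0, 12.0, 15.3, 20.0, 30.0])
        cat, cuts = discretize_by_control_quantiles(
            controls, np.ones(7, bool), 3)
        assert np.allclose(cuts, [9.0, 15.3])
        assert list(cat.categories) == ["<9.0", "9.0–15.3", "≥15.3"]
        # boundary values fall in the upper (left-closed) bin
        assert str(cat[2]) == "9.0–15.3"

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x ** 3,
                                           lambda x: -1.0 / (x + 50)])
    def test_invariant_under_strictly_monotone_transform(self, rng, transform):
        values = rng.normal(size=400) * 10
        control = rng.random(400) < 0.6
        base, _ = discretize_by_control_quantiles(values, control, 4)
        trans, _ = discretize_by_control_quantiles(transform(values), control, 4)
        assert (base.codes == trans.codes).all()

    def test_control_category_counts_near_equal(self, rng):
        values = rng.gamma(2.0, size=801)
        control = np.zeros(801, bool)
        control[:600] = True
        cat, _ = discretize_by_control_quantiles(values, control, 4)
        counts = np.bincount(cat.codes[control], minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_missing_values_stay_missing(self):
        values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, np.nan])
        cat, _ = discretize_by_control_quantiles(values, ~np.isnan(values), 4)
        assert pd.isna(pd.Series(cat).iloc[-1])


class TestCollapseGenotypes:
    def test_rare_homozygous_merged(self):
        col = pd.Categorical(["0"] * 1500 + ["1"] * 260 + ["2"] * 4)
        out = collapse_rare_genotypes(col, min_homozygous=40)
        counts = pd.Series(out).value_counts()
        assert counts["common"] == 1500 and counts["variant"] == 264

    def test_common_genotypes_unchanged(self):
        col = pd.Categorical(["0"] * 900 + ["1"] * 600 + ["2"] * 300)
        out = collapse_rare_genotypes(col, min_homozygous=40)
        assert list(out.categories) == ["0", "1", "2"]

    def test_degenerate_all_homozygous_variant(self):
        col = pd.Categorical(["2"] * 50, categories=["0", "1", "2"])
        out = collapse_rare_genotypes(col, min_homozygous=100)
        assert list(pd.unique(pd.Series(out).dropna())) == ["variant"]


class TestHWE:
    def test_exact_hwe_proportions_give_zero_statistic(self):
        stat, p = hwe_test((25, 50, 25))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        stat, p = hwe_test((10, 10, 10))
        assert stat == pytest.approx(10 / 3, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(10 / 3, 1), rel=1e-9)

    def test_small_expected_counts_use_exact_test(self):
        stat, p = hwe_test((98, 1, 1))
        assert math.isnan(stat)  # exact branch
        assert 0.0 < p <= 1.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))

    def test_p_uniform_under_null(self, rng):
        # genotype draws from exact HWE proportions; the chi-square p-value
        # should be (approximately) uniform
        q, n = 0.3, 1000
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
        ps = []
        for _ in range(5000):
            counts = rng.multinomial(n, probs)
            ps.append(hwe_test(counts)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def test_bonferroni_thresholds():
    assert round(bonferroni_threshold(0.05, 14), 3) == 0.004
    assert round(bonferroni_threshold(0.05, 34), 4) == 0.0015
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


class TestSpearman:
    def test_self_correlation_unity_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        rep = spearman_matrix(df)
        assert np.allclose(np.diag(rep.spearman), 1.0)
        assert np.allclose(rep.spearman, rep.spearman.T)

    def test_hand_computed_rank_correlation(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4: r = 1 - 6*4/(5*24) = 0.8
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        assert spearman_matrix(df).spearman.loc["x", "y"] == \
            pytest.approx(0.8, abs=1e-12)

    def test_monotone_nonlinear_pair_perfect(self):
        x = np.linspace(0.1, 5, 40)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        assert spearman_matrix(df).spearman.loc["x", "y"] == pytest.approx(1.0)

    def test_pairwise_complete_and_linkage_monotone(self, rng):
        df = pd.DataFrame(rng.normal(size=(120, 5)),
                          columns=list("abcde"))
        df.loc[:30, "a"] = np.nan
        rep = spearman_matrix(df)
        assert rep.n_pairs.loc["a", "b"] < rep.n_pairs.loc["b", "c"]
        heights = rep.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()  # complete linkage


class TestBaselineComparison:
    def _table(self, case_vals, ctrl_vals):
        from bnepi.cohort import CohortTable

        n1, n0 = len(case_vals), len(ctrl_vals)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n1 + n0)],
            "matched_set_id": ["m"] * (n1 + n0),
            "crc": ["1"] * n1 + ["0"] * n0,
            "val_conc": list(case_vals) + list(ctrl_vals),
        })
        return CohortTable(df, {"crc": "outcome"})

    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 5
        t = self._table(vals, vals)
        rep = baseline_comparison(t, t.data[["val_conc"]])
        assert rep.loc[0, "p"] == pytest.approx(1.0)

    def test_chi_square_without_continuity_correction(self):
        obs = np.array([[30, 10], [10, 30]])
        chi2, _, _, _ = stats.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(20.0)

    def test_adjusted_threshold_counts_metabolite_tests(self, bench_cohort):
        cont = bench_cohort.table.data[
            [c for c in bench_cohort.table.data.columns
             if c.endswith("_conc")]]
        rep = baseline_comparison(bench_cohort.table, cont)
        mw = rep[rep["test"] == "mann-whitney"]
        assert len(mw) == 14
        assert mw["adjusted_threshold"].iloc[0] == pytest.approx(0.05 / 14)
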