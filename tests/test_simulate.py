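"""Synthetic cohort generator: HWE, LD, copula targets, matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bnepi.epi import clr_fit
from bnepi.prep import hwe_test, spearman_matrix
from bnepi.simulate import (LOGNORMAL_MARGINALS, TruthSpec,
                            generate_genotypes, generate_metabolites,
                            generate_cohort, pearson_to_spearman,
                            simulate_matched_sets, spearman_to_pearson)


class TestGenotypes:
    def test_hwe_proportions_at_half_maf(self, rng):
        g = generate_genotypes([0.5], [], 200_000, rng)
        freq = np.bincount(g[:, 0], minlength=3) / 200_000
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=0.005)

    def test_hwe_chi_square_rarely_rejects(self, rng):
        # generated genotypes should pass the HWE check essentially always
        fails = 0
        reps = 500
        for _ in range(reps):
            g = generate_genotypes([0.3], [], 10_000, rng)
            _stat, p = hwe_test(np.bincount(g[:, 0], minlength=3))
            fails += p <= 0.001
        assert fails / reps <= 0.01

    def test_perfect_ld_equal_maf_identical_vectors(self, rng):
        g = generate_genotypes([0.3, 0.3], [(0, 1, 1.0)], 5000, rng)
        assert (g[:, 0] == g[:, 1]).all()

    def test_requested_haplotype_correlation(self, rng):
        g = generate_genotypes([0.3, 0.4], [(0, 1, 0.25)], 200_000, rng)
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.01)

    def test_infeasible_ld_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_genotypes([0.05, 0.45], [(0, 1, 0.9)], 100, seed=0)

    def test_invalid_maf_raises(self):
        with pytest.raises(ValueError, match="0, 0.5"):
            generate_genotypes([0.7], [], 10, seed=0)


class TestMetabolites:
    def test_identity_correlation_gives_independence(self, rng):
        df, _ = generate_metabolites(np.eye(14), [], None, 50_000, rng)
        r = spearman_matrix(df).spearman.to_numpy()
        off = r[~np.eye(14, dtype=bool)]
        assert np.max(np.abs(off)) < 0.02

    def test_published_spearman_targets_hit(self, rng):
        spec = TruthSpec(seed=0)
        df, _ = generate_metabolites(spec.latent_corr, [], None, 50_000, rng,
                                     metabolite_names=spec.metabolites)
        r = spearman_matrix(df).spearman
        assert r.loc["glycine", "serine"] == pytest.approx(0.52, abs=0.03)
        assert r.loc["choline", "betaine"] == pytest.approx(0.40, abs=0.03)
        assert r.loc["folate", "homocysteine"] == pytest.approx(-0.37, abs=0.03)

    def test_sin_transform_round_trip(self):
        assert pearson_to_spearman(spearman_to_pearson(0.52)) == \
            pytest.approx(0.52, abs=1e-12)

    def test_genotype_shift_in_latent_sd_units(self, rng):
        spec = TruthSpec(seed=0)
        g = generate_genotypes([0.5], [], 50_000, rng)
        df, latent = generate_metabolites(
            spec.latent_corr, [(0, "homocysteine", 0.5)], g, 50_000, rng,
            metabolite_names=spec.metabolites)
        j = spec.metabolites.index("homocysteine")
        hcy = latent[:, j]
        diff = hcy[g[:, 0] == 2].mean() - hcy[g[:, 0] == 0].mean()
        within_sd = np.std(hcy[g[:, 0] == 0])
        assert diff / within_sd == pytest.approx(1.0, abs=0.05)
        # assay-scale values are a monotone (log-normal) transform
        mu, sig = LOGNORMAL_MARGINALS["homocysteine"]
        assert np.allclose(np.log(df["homocysteine"]), mu + sig * hcy)

    def test_non_psd_matrix_raises_naming_eigenvalue(self):
        bad = np.array([[1.0, 0.99, -0.99],
                        [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_metabolites(bad, [], None, 10, seed=0,
                                 metabolite_names=["a", "b", "c"])


class TestOutcomeAndMatching:
    def test_matched_sets_balanced_and_sized(self, bench_cohort):
        t = bench_cohort.table
        for _, grp in t.data.groupby("matched_set_id"):
            assert (grp["crc"].astype(str) == "1").sum() == 1
            for v in ("sex", "cohort", "fasting", "year_group"):
                assert grp[v].nunique() == 1
            ages = grp["age"].to_numpy()
            case_age = ages[(grp["crc"].astype(str) == "1").to_numpy()][0]
            assert np.all(np.abs(ages - case_age) <= 64 * 2.0)

    def test_control_count_arithmetic(self, bench_cohort):
        assert bench_cohort.n_cases == 300
        assert bench_cohort.n_controls + bench_cohort.shortfall == 600

    def test_null_model_no_case_control_differences(self):
        spec = TruthSpec(seed=42, outcome_log_or={}, interaction=None)
        co = generate_cohort(spec, n_cases=250)
        case = np.asarray(co.table.case_mask)
        ps = []
        for m in co.continuous_metabolites.columns:
            x = co.continuous_metabolites[m].to_numpy()
            ps.append(stats.mannwhitneyu(x[case], x[~case],
                                         alternative="two-sided").pvalue)
        # under the null nothing clears the Bonferroni threshold
        assert min(ps) > 0.05 / 14

    def test_null_truth_yields_no_outcome_edges_above_threshold(self):
        # with every outcome coefficient zero, the averaged network must
        # retain no relation between the outcome and anything else
        from bnepi.average import bootstrap_confidences, estimate_threshold
        from bnepi.prep import discretize_cohort

        for seed in (60, 61, 62):
            spec = TruthSpec(seed=seed, outcome_log_or={}, interaction=None)
            co = generate_cohort(spec, n_cases=150)
            table, _ = discretize_cohort(co.table, k=4)
            codes, cards, names = table.encoded()
            conf = bootstrap_confidences(codes, cards, names, algorithm="hc",
                                         B=40,
                                         seed=np.random.default_rng(seed))
            thr = estimate_threshold(list(conf.undirected.values()))
            crc_confs = [c for p, c in conf.undirected.items() if "crc" in p]
            assert max(crc_confs, default=0.0) <= thr

    def test_clr_recovers_generator_coefficient(self):
        # single-effect truth: the per-SD log OR is identified by CLR on
        # the latent (log-scale standardized) concentration
        spec = TruthSpec(seed=7,
                         outcome_log_or={"vitamin_B2": -0.3},
                         interaction=None)
        co = generate_cohort(spec, n_cases=600)
        df = co.table.data.copy()
        df["_case"] = np.asarray(co.table.case_mask, int)
        mu, sig = LOGNORMAL_MARGINALS["vitamin_B2"]
        df["z_b2"] = (np.log(df["vitamin_B2_conc"]) - mu) / sig
        fit = clr_fit(df, ["z_b2"])
        beta, se = fit.params.iloc[0], fit.se.iloc[0]
        assert abs(beta - (-0.3)) < 2 * se

    def test_truth_dag_matches_generating_equations(self):
        spec = TruthSpec(seed=0)
        dag = spec.truth_dag()
        assert dag.has_edge("folate", "crc")
        assert dag.has_edge("MTHFR_677CT", "homocysteine")
        assert dag.has_edge("serine", "glycine")
        assert dag.has_edge("cohort", "fasting")
        assert ("crc", "folate") not in dag.edges


class TestMatchedSetSimulator:
    def test_case_probabilities_follow_conditional_model(self, rng):
        # the frequency with which the highest-x subject is the case must
        # match the mean softmax probability of that subject (the model)
        d = simulate_matched_sets(2000, 2, [5.0], rng)
        hit, expected = 0, 0.0
        for _, g in d.groupby("set_id"):
            w = np.exp(5.0 * g["x0"].to_numpy())
            expected += w.max() / w.sum()
            hit += g.loc[g["x0"].idxmax(), "case"] == 1
        assert hit / 2000 == pytest.approx(expected / 2000, abs=0.03)
        d0 = simulate_matched_sets(3000, 2, [0.0], rng)
        first = d0.groupby("set_id").apply(
            lambda g: int(g["case"].to_numpy()[0]), include_groups=False)
        assert abs(first.mean() - 1 / 3) < 0.03
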