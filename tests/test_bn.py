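"""Graph and probability primitives: scoring, testing, CPTs, inference."""

import itertools
import math

import numpy as np
import pytest

from bnepi.bn import (DAG, DiscreteBN, aic_score, mi_ci_test, fit_cpts,
                      query_conditional, forward_sample, read_sif, write_sif,
                      write_graphml)

from conftest import brute_force_conditional, random_bn


# ---------------------------------------------------------------------------
# DAG type
# ---------------------------------------------------------------------------

class TestDAG:
    def test_rejects_cycles_self_loops_duplicates(self):
        d = DAG(["a", "b", "c"], [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError):
            d.add_edge("c", "a")
        with pytest.raises(ValueError):
            d.add_edge("a", "a")
        with pytest.raises(ValueError):
            d.add_edge("a", "b")

    def test_topological_order_and_skeleton(self):
        d = DAG(["x", "y", "z"], [("z", "y"), ("y", "x")])
        assert d.topological_order() == ["z", "y", "x"]
        assert d.skeleton() == {frozenset(("z", "y")), frozenset(("y", "x"))}


# ---------------------------------------------------------------------------
# AIC score
# ---------------------------------------------------------------------------

class TestAicScore:
    def test_single_binary_node_closed_form(self):
        codes = np.array([[0]] * 50 + [[1]] * 50)
        total, fams = aic_score(DAG(["a"]), codes, [2], ["a"])
        assert total == pytest.approx(100 * math.log(0.5) - 1, abs=1e-9)
        assert fams["a"] == pytest.approx(total)

    def test_decomposable(self, rng):
        codes = rng.integers(0, 3, size=(300, 3))
        dag = DAG(["a", "b", "c"], [("a", "b"), ("b", "c")])
        total, fams = aic_score(dag, codes, [3, 3, 3], ["a", "b", "c"])
        assert total == pytest.approx(sum(fams.values()), abs=1e-12)

    def test_markov_equivalent_dags_score_identically(self, rng):
        # the three no-collider orientations of the chain a-b-c are one
        # equivalence class; the collider is a different class
        codes = rng.integers(0, 2, size=(400, 3))
        cards, names = [2, 2, 2], ["a", "b", "c"]
        chain1 = DAG(names, [("a", "b"), ("b", "c")])
        chain2 = DAG(names, [("c", "b"), ("b", "a")])
        fork = DAG(names, [("b", "a"), ("b", "c")])
        scores = [aic_score(d, codes, cards, names)[0]
                  for d in (chain1, chain2, fork)]
        assert max(scores) - min(scores) < 1e-9

    def test_empty_beats_single_edge_on_independent_columns(self, rng):
        codes = rng.integers(0, 4, size=(5000, 2))
        cards, names = [4, 4], ["a", "b"]
        empty, _ = aic_score(DAG(names), codes, cards, names)
        one, _ = aic_score(DAG(names, [("a", "b")]), codes, cards, names)
        assert empty >= one

    def test_unseen_parent_config_counts_parameters(self):
        # parent category 2 never observed: likelihood ignores it but the
        # penalty still charges (2-1)*3 parameters for the family
        codes = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 10)
        dag = DAG(["p", "x"], [("p", "x")])
        total, fams = aic_score(dag, codes, [3, 2], ["p", "x"])
        loglik = 40 * math.log(0.5)  # x is 50/50 within both observed strata
        assert fams["x"] == pytest.approx(loglik - 3, abs=1e-9)


# ---------------------------------------------------------------------------
# G² conditional-independence test
# ---------------------------------------------------------------------------

class TestG2:
    def test_hand_computed_2x2(self):
        codes = np.array([[0, 0]] * 30 + [[0, 1]] * 10
                         + [[1, 0]] * 10 + [[1, 1]] * 30)
        res = mi_ci_test(codes, [2, 2], 0, 1)
        mi = 0.75 * math.log(1.5) + 0.25 * math.log(0.5)
        assert res.statistic == pytest.approx(160 * mi, rel=1e-9)
        assert res.df == 1

    def test_constant_column_gives_zero_information(self):
        codes = np.column_stack([np.arange(40) % 4, np.zeros(40, int)])
        res = mi_ci_test(codes, [4, 2], 0, 1)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_additive_over_conditioning_strata(self, rng):
        codes = np.column_stack([
            rng.integers(0, 3, 600), rng.integers(0, 3, 600),
            rng.integers(0, 2, 600)])
        cards = [3, 3, 2]
        whole = mi_ci_test(codes, cards, 0, 1, (2,))
        parts = sum(
            mi_ci_test(codes[codes[:, 2] == z], cards, 0, 1).statistic
            for z in (0, 1))
        assert whole.statistic == pytest.approx(parts, rel=1e-9)
        assert whole.df == 2 * 2 * 2

    def test_invariant_to_category_relabeling(self, rng):
        codes = rng.integers(0, 3, size=(500, 2))
        base = mi_ci_test(codes, [3, 3], 0, 1).statistic
        perm = np.array([2, 0, 1])
        relabeled = np.column_stack([perm[codes[:, 0]], codes[:, 1]])
        assert mi_ci_test(relabeled, [3, 3], 0, 1).statistic == \
            pytest.approx(base, rel=1e-12)

    def test_null_calibration_quick(self, rng):
        # nominal alpha within Monte-Carlo tolerance at a reduced replicate
        # count (the full-resolution calibration lives in the acceptance
        # suite)
        rej = 0
        sims = 1000
        for _ in range(sims):
            codes = np.column_stack([rng.integers(0, 4, 400),
                                     rng.integers(0, 4, 400)])
            if mi_ci_test(codes, [4, 4], 0, 1).p <= 0.05:
                rej += 1
        assert abs(rej / sims - 0.05) < 0.025


# ---------------------------------------------------------------------------
# CPT estimation
# ---------------------------------------------------------------------------

class TestFitCpts:
    def test_no_parent_relative_frequencies(self):
        codes = np.array([[0]] * 60 + [[1]] * 40)
        bn = fit_cpts(DAG(["a"]), codes, [2], ["a"])
        assert np.allclose(bn.cpts["a"], [0.6, 0.4])

    def test_add_one_smoothing_closed_form(self):
        codes = np.array([[1]] * 10)
        bn = fit_cpts(DAG(["a"]), codes, [2], ["a"], smoothing=1.0)
        assert np.allclose(bn.cpts["a"], [1 / 12, 11 / 12])

    def test_unseen_parent_config_warns_and_uniform(self):
        codes = np.array([[0, 0], [0, 1], [0, 0], [0, 1]])
        dag = DAG(["p", "x"], [("p", "x")])
        with pytest.warns(UserWarning, match="unseen parent"):
            bn = fit_cpts(dag, codes, [2, 2], ["p", "x"])
        assert np.allclose(bn.cpts["x"][1], [0.5, 0.5])

    def test_recovery_from_large_sample(self, rng):
        # chain structure keeps every parent configuration well populated,
        # so the law of large numbers bites at this sample size
        dag = DAG(["a", "b", "c"], [("a", "b"), ("b", "c")])
        cpts = {"a": np.array([0.5, 0.3, 0.2]),
                "b": np.array([[0.6, 0.4], [0.3, 0.7], [0.5, 0.5]]),
                "c": np.array([[0.2, 0.5, 0.3], [0.7, 0.2, 0.1]])}
        bn = DiscreteBN(dag, cpts, {v: None for v in "abc"})
        data = forward_sample(bn, 100_000, rng)
        names = list(bn.dag.nodes)
        codes = np.column_stack([data[v] for v in names])
        cards = [bn.card(v) for v in names]
        refit = fit_cpts(bn.dag, codes, cards, names, smoothing=0.0)
        for v in names:
            assert np.max(np.abs(refit.cpts[v] - bn.cpts[v])) < 0.01


# ---------------------------------------------------------------------------
# Exact inference
# ---------------------------------------------------------------------------

class TestQueryConditional:
    @pytest.fixture
    def chain(self):
        dag = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        cpts = {"A": np.array([0.6, 0.4]),
                "B": np.array([[0.7, 0.3], [0.2, 0.8]]),
                "C": np.array([[0.9, 0.1], [0.4, 0.6]])}
        return DiscreteBN(dag, cpts, {v: ["0", "1"] for v in "ABC"})

    def test_chain_marginalization_by_hand(self, chain):
        got = query_conditional(chain, "C", {"A": "0"})
        hand = chain.cpts["B"][0] @ chain.cpts["C"]
        assert np.allclose(got, hand, atol=1e-12)

    def test_d_separated_evidence_returns_marginal(self, chain):
        # C is independent of A given B
        for b in ("0", "1"):
            with_a = query_conditional(chain, "C", {"B": b, "A": "1"})
            without = query_conditional(chain, "C", {"B": b})
            assert np.allclose(with_a, without, atol=1e-12)

    def test_zero_probability_evidence_raises(self):
        dag = DAG(["A", "B"], [("A", "B")])
        cpts = {"A": np.array([1.0, 0.0]),
                "B": np.array([[0.5, 0.5], [0.5, 0.5]])}
        bn = DiscreteBN(dag, cpts, {"A": ["0", "1"], "B": ["0", "1"]})
        with pytest.raises(ValueError, match="probability zero"):
            query_conditional(bn, "B", {"A": "1"})

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        bn = random_bn(rng, int(rng.integers(3, 7)))
        names = list(bn.dag.nodes)
        target = names[int(rng.integers(len(names)))]
        n_ev = int(rng.integers(0, 3))
        ev_vars = [v for v in names if v != target][:n_ev]
        evidence = {v: int(rng.integers(bn.card(v))) for v in ev_vars}
        try:
            got = query_conditional(bn, target, evidence)
        except ValueError:
            return  # zero-probability evidence; oracle undefined too
        want = brute_force_conditional(bn, target, evidence)
        assert np.allclose(got, want, atol=1e-10)

    def test_prior_matches_forward_sampling(self, rng):
        bn = random_bn(rng, 5)
        v = bn.dag.nodes[-1]
        exact = query_conditional(bn, v, {})
        n = 200_000
        samples = forward_sample(bn, n, rng)[v]
        freq = np.bincount(samples, minlength=bn.card(v)) / n
        mc_se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freq - exact) < 3 * mc_se + 1e-12)


# ---------------------------------------------------------------------------
# Import / export
# ---------------------------------------------------------------------------

def test_sif_round_trip(tmp_path):
    dag = DAG(["a", "b", "c"], [("a", "b"), ("c", "b")])
    path = tmp_path / "net.sif"
    write_sif(dag.edges, path)
    back = read_sif(path, nodes=dag.nodes)
    assert back.edges == dag.edges


def test_graphml_export_has_confidence(tmp_path):
    import networkx as nx

    dag = DAG(["a", "b"], [("a", "b")])
    path = tmp_path / "net.graphml"
    write_graphml(dag, path, confidence={("a", "b"): 0.83})
    g = nx.read_graphml(path)
    assert g["a"]["b"]["confidence"] == pytest.approx(0.83)
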