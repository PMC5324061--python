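"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from bnepi.bn import DAG, DiscreteBN
from bnepi.prep import discretize_cohort
from bnepi.simulate import TruthSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Benchmark cohort (session-scoped: several module suites reuse it)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bench_cohort():
    spec = TruthSpec(seed=11)
    return generate_cohort(spec, n_cases=300)


@pytest.fixture(scope="session")
def bench_table(bench_cohort):
    table, _cutoffs = discretize_cohort(bench_cohort.table, k=4)
    return table


# ---------------------------------------------------------------------------
# Random discrete BNs and a brute-force inference oracle
# ---------------------------------------------------------------------------

def random_bn(rng: np.random.Generator, n_nodes: int, max_card: int = 3,
              edge_prob: float = 0.4) -> DiscreteBN:
    """A random DAG (edges respect a random node order) with Dirichlet CPTs."""
    names = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    dag = DAG(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            u, v = names[order[i]], names[order[j]]
            dag.add_edge(u, v)
    cards = {v: int(rng.integers(2, max_card + 1)) for v in names}
    cpts = {}
    for v in names:
        ps = dag.parents(v)
        shape = tuple(cards[p] for p in ps) + (cards[v],)
        t = rng.gamma(1.0, size=shape) + 0.05
        cpts[v] = t / t.sum(axis=-1, keepdims=True)
    levels = {v: [str(i) for i in range(cards[v])] for v in names}
    return DiscreteBN(dag=dag, cpts=cpts, levels=levels)


def joint_table(bn: DiscreteBN) -> tuple[np.ndarray, list[str]]:
    """Full joint probability table by explicit enumeration (the oracle)."""
    names = list(bn.dag.nodes)
    cards = [bn.card(v) for v in names]
    joint = np.zeros(cards)
    for assign in itertools.product(*(range(c) for c in cards)):
        p = 1.0
        for k, v in enumerate(names):
            idx = tuple(assign[names.index(q)] for q in bn.dag.parents(v))
            p *= bn.cpts[v][idx + (assign[k],)]
        joint[assign] = p
    return joint, names


def brute_force_conditional(bn: DiscreteBN, target: str, evidence: dict
                            ) -> np.ndarray:
    """P(target | evidence) from the enumerated joint."""
    joint, names = joint_table(bn)
    slicer = []
    for v in names:
        if v in evidence:
            slicer.append(bn.level_index(v, evidence[v]))
        else:
            slicer.append(slice(None))
    sub = joint[tuple(slicer)]
    free = [v for v in names if v not in evidence]
    axis = tuple(i for i, v in enumerate(free) if v != target)
    marg = sub.sum(axis=axis) if axis else sub
    return marg / marg.sum()


def all_dags_3(names=("a", "b", "c")) -> list[DAG]:
    """All 25 DAGs on three labelled nodes."""
    names = list(names)
    pairs = [(names[0], names[1]), (names[0], names[2]),
             (names[1], names[2])]
    out = []
    for states in itertools.product([0, 1, 2], repeat=3):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        try:
            out.append(DAG(names, edges))
        except ValueError:
            continue
    assert len(out) == 25
    return out


def sample_from_bn(bn: DiscreteBN, n: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ancestral samples as (codes, cards, names) for the learners."""
    from bnepi.bn import forward_sample

    data = forward_sample(bn, n, rng)
    names = list(bn.dag.nodes)
    codes = np.column_stack([data[v] for v in names]).astype(np.int64)
    cards = np.array([bn.card(v) for v in names])
    return codes, cards, names
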