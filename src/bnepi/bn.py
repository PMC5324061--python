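"""Discrete Bayesian-network primitives.

This module provides the probabilistic core used by the structure-learning
and inference stages:

* :class:`DAG` — a directed acyclic graph over named variables;
* decomposable AIC scoring of a DAG against a fully observed categorical
  table (multinomial maximum likelihood per node family, penalty of one per
  free parameter);
* the asymptotic chi-square mutual-information test of conditional
  independence (the G² statistic ``2·N·MI(x; y | Z)``);
* :class:`DiscreteBN` — a DAG plus conditional probability tables, with
  maximum-likelihood / add-alpha estimation, exact conditional queries by
  variable elimination, and forward sampling;
* SIF and GraphML import/export.

Scores and tests operate on integer-coded matrices (see
:meth:`bnepi.cohort.CohortTable.encoded`) for speed: a hill-climbing run
evaluates thousands of node families, each reduced to one ``bincount`` over
a mixed-radix joint index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "DAG",
    "DiscreteBN",
    "CITestResult",
    "ScoreCache",
    "aic_score",
    "mi_ci_test",
    "fit_cpts",
    "query_conditional",
    "forward_sample",
    "write_sif",
    "read_sif",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------

class DAG:
    """Directed acyclic graph over an ordered set of variable names."""

    def __init__(self, nodes, edges=()):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- mutation ----------------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r}")
        if v in self._parents and u in self._parents[v]:
            raise ValueError(f"duplicate edge {u!r}->{v!r}")
        if self.has_path(v, u):
            raise ValueError(f"edge {u!r}->{v!r} would create a cycle")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_edge(self, u: str, v: str) -> None:
        self._parents[v].remove(u)
        self._children[u].remove(v)

    # -- queries -----------------------------------------------------------

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[v]))

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(self._children[v]))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for v, ps in self._parents.items() for u in ps}

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def has_path(self, u: str, v: str) -> bool:
        """True if a directed path u -> ... -> v exists (including u == v)."""
        if u == v:
            return True
        stack, seen = [u], {u}
        while stack:
            w = stack.pop()
            for c in self._children[w]:
                if c == v:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def topological_order(self) -> list[str]:
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        ready = sorted(v for v in self.nodes if indeg[v] == 0)
        order: list[str] = []
        while ready:
            v = ready.pop(0)
            order.append(v)
            for c in sorted(self._children[v]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            ready.sort()
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def copy(self) -> "DAG":
        return DAG(self.nodes, self.edges)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DAG) and self.nodes == other.nodes
                and self.edges == other.edges)

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.edges)} edges)"


# ---------------------------------------------------------------------------
# Family scores (decomposable AIC)
# ---------------------------------------------------------------------------

class ScoreCache:
    """Cached per-family AIC scores for one coded data matrix.

    The AIC convention is maximized ``logLik - k`` with ``k`` one per free
    parameter: a node with cardinality ``c`` and parent configurations ``q``
    contributes ``(c - 1) * q`` parameters.  Parent configurations never
    observed in the data contribute zero log-likelihood but their parameters
    still count, which keeps the score decomposable and equal across
    Markov-equivalent structures.
    """

    def __init__(self, codes: np.ndarray, cards: np.ndarray, names: list[str]):
        self.codes = np.ascontiguousarray(codes, dtype=np.int64)
        self.cards = np.asarray(cards, dtype=np.int64)
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n = self.codes.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = self._compute(child, key[1])
        self._cache[key] = val
        return val

    def _compute(self, child: int, parents: tuple[int, ...]) -> float:
        c = int(self.cards[child])
        q = 1
        joint = self.codes[:, child].copy()
        radix = c
        for p in parents:
            cp = int(self.cards[p])
            joint += radix * self.codes[:, p]
            radix *= cp
            q *= cp
        counts = np.bincount(joint, minlength=c * q).reshape(q, c)
        row_tot = counts.sum(axis=1)
        nz = counts > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.sum(counts[nz] * np.log(
                counts[nz] / row_tot[:, None].repeat(c, 1)[nz])))
        params = (c - 1) * q
        return ll - params


def aic_score(dag: DAG, codes, cards, names) -> tuple[float, dict[str, float]]:
    """Total AIC score of ``dag`` and the per-node family scores.

    Decomposable: the total equals the sum of the per-family terms, and
    Markov-equivalent DAGs receive identical totals.
    """
    cache = codes if isinstance(codes, ScoreCache) else ScoreCache(codes, cards, names)
    fam: dict[str, float] = {}
    for v in dag.nodes:
        ci = cache.index[v]
        ps = tuple(cache.index[p] for p in dag.parents(v))
        fam[v] = cache.family_score(ci, ps)
    return sum(fam.values()), fam


# ---------------------------------------------------------------------------
# Conditional-independence test (G² / mutual information)
# ---------------------------------------------------------------------------

@dataclass
class CITestResult:
    """Result of the asymptotic chi-square mutual-information test."""
    statistic: float
    df: int
    p: float


def encode_strata(codes, cards, zs) -> tuple[np.ndarray, int]:
    """Mixed-radix joint code of the conditioning variables ``zs``.

    Precomputing this once lets many tests against the same conditioning
    set share the encoding (the learners' hot loop).
    """
    nz = 1
    zcode = np.zeros(np.asarray(codes).shape[0], dtype=np.int64)
    for z in zs:
        zcode = zcode * int(cards[z]) + codes[:, z]
        nz *= int(cards[z])
    return zcode, nz


def _g2_sum_python(xcol, ycol, cx, cy, zcode, nz) -> float:
    joint = (zcode * cx + xcol) * cy + ycol
    counts = np.bincount(joint, minlength=nz * cx * cy).reshape(nz, cx, cy)
    n_z = counts.sum(axis=(1, 2), keepdims=True)
    n_xz = counts.sum(axis=2, keepdims=True)
    n_yz = counts.sum(axis=1, keepdims=True)
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * n_z / (n_xz * n_yz)
        return 2.0 * float(np.sum(counts[mask] * np.log(ratio[mask])))


try:  # jitted kernel for the structure learners' hot loop
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _g2_sum_jit(xcol, ycol, cx, cy, zcode, nz):  # pragma: no cover
        counts = np.zeros(nz * cx * cy, dtype=np.float64)
        for i in range(xcol.shape[0]):
            counts[(zcode[i] * cx + xcol[i]) * cy + ycol[i]] += 1.0
        n_z = np.zeros(nz)
        n_xz = np.zeros(nz * cx)
        n_yz = np.zeros(nz * cy)
        for z in range(nz):
            for a in range(cx):
                for b in range(cy):
                    c = counts[(z * cx + a) * cy + b]
                    n_z[z] += c
                    n_xz[z * cx + a] += c
                    n_yz[z * cy + b] += c
        g2 = 0.0
        for z in range(nz):
            for a in range(cx):
                for b in range(cy):
                    c = counts[(z * cx + a) * cy + b]
                    if c > 0.0:
                        g2 += c * np.log(c * n_z[z]
                                         / (n_xz[z * cx + a] * n_yz[z * cy + b]))
        return 2.0 * g2

    _g2_sum = _g2_sum_jit
except Exception:  # pragma: no cover - numba is an optional accelerator
    _g2_sum = _g2_sum_python


def g2_statistic(xcol: np.ndarray, ycol: np.ndarray, cx: int, cy: int,
                 zcode: np.ndarray, nz: int) -> tuple[float, int, float]:
    """(G², df, p) for two coded columns within precomputed strata."""
    g2 = max(float(_g2_sum(np.ascontiguousarray(xcol, dtype=np.int64),
                           np.ascontiguousarray(ycol, dtype=np.int64),
                           cx, cy, zcode, nz)), 0.0)
    df = max((cx - 1) * (cy - 1) * nz, 1)
    p = float(special.chdtrc(df, g2)) if g2 > 0 else 1.0
    return g2, df, p


def mi_ci_test(codes, cards, x: int, y: int, zs: tuple[int, ...] = ()
               ) -> CITestResult:
    """G² test of ``x`` independent of ``y`` given ``zs`` on coded data.

    ``G² = 2·N·MI(x; y | Z)`` summed over observed Z strata, with degrees of
    freedom ``(|x|-1)(|y|-1)·prod(|z|)``.  Empty strata contribute zero to
    the statistic; the degrees of freedom are not reduced for them (a fixed
    convention so results are reproducible across resamples).
    """
    codes = np.asarray(codes)
    zcode, nz = encode_strata(codes, cards, zs)
    g2, df, p = g2_statistic(codes[:, x], codes[:, y], int(cards[x]),
                             int(cards[y]), zcode, nz)
    return CITestResult(statistic=g2, df=df, p=p)


# ---------------------------------------------------------------------------
# Conditional probability tables
# ---------------------------------------------------------------------------

@dataclass
class DiscreteBN:
    """A DAG with per-node conditional probability tables.

    ``cpts[v]`` has shape ``(*parent_cards, card_v)`` with parents in the
    order given by ``dag.parents(v)`` (sorted by name); each row along the
    last axis sums to one.  ``levels[v]`` lists the category labels.
    """

    dag: DAG
    cpts: dict[str, np.ndarray]
    levels: dict[str, list[str]] = field(default_factory=dict)

    def card(self, v: str) -> int:
        return self.cpts[v].shape[-1]

    def validate(self, atol: float = 1e-12) -> None:
        for v in self.dag.nodes:
            t = self.cpts[v]
            expect = tuple(self.card(p) for p in self.dag.parents(v)) + (self.card(v),)
            if t.shape != expect:
                raise ValueError(f"CPT shape mismatch for {v!r}: {t.shape} != {expect}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=atol):
                raise ValueError(f"CPT rows for {v!r} do not sum to 1")

    def level_index(self, v: str, value) -> int:
        if isinstance(value, (int, np.integer)):
            return int(value)
        return self.levels[v].index(str(value))


def fit_cpts(dag: DAG, codes, cards, names, smoothing: float = 0.0,
             levels: dict[str, list[str]] | None = None) -> DiscreteBN:
    """Estimate CPTs by (smoothed) relative frequencies.

    With ``smoothing=0`` raw maximum-likelihood frequencies are returned and
    parent configurations never observed get a uniform row (with a warning);
    with ``smoothing=alpha > 0`` every cell count is incremented by alpha.
    """
    index = {n: i for i, n in enumerate(names)}
    codes = np.asarray(codes, dtype=np.int64)
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        ci = index[v]
        ps = dag.parents(v)
        c = int(cards[ci])
        pcards = [int(cards[index[p]]) for p in ps]
        q = int(np.prod(pcards)) if pcards else 1
        joint = codes[:, ci].copy()
        radix = c
        for p, cp in zip(ps, pcards):
            joint += radix * codes[:, index[p]]
            radix *= cp
        counts = np.bincount(joint, minlength=c * q).reshape(
            tuple(reversed(pcards)) + (c,) if pcards else (c,))
        if pcards:
            # bincount radix order is (last parent slowest); transpose back
            counts = counts.transpose(tuple(range(len(pcards) - 1, -1, -1)) + (len(pcards),))
        counts = counts.astype(float) + smoothing
        tot = counts.sum(axis=-1, keepdims=True)
        empty = (tot == 0)
        if empty.any():
            if smoothing == 0:
                warnings.warn(
                    f"unseen parent configuration(s) for {v!r}; uniform rows used",
                    stacklevel=2)
            counts = np.where(empty, 1.0, counts)
            tot = counts.sum(axis=-1, keepdims=True)
        cpts[v] = counts / tot
    lv = levels or {v: [str(i) for i in range(int(cards[index[v]]))] for v in dag.nodes}
    return DiscreteBN(dag=dag, cpts=cpts, levels=lv)


# ---------------------------------------------------------------------------
# Exact inference by variable elimination
# ---------------------------------------------------------------------------

class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = tuple(variables)
        self.values = values


def _multiply(factors: list[_Factor]) -> _Factor:
    all_vars: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in all_vars:
                all_vars.append(v)
    shape = {}
    for f in factors:
        for v, s in zip(f.vars, f.values.shape):
            shape[v] = s
    out = np.ones(tuple(shape[v] for v in all_vars))
    for f in factors:
        idx = tuple(
            slice(None) if v in f.vars else None for v in all_vars)
        # move f axes into all_vars order
        perm = sorted(range(len(f.vars)), key=lambda i: all_vars.index(f.vars[i]))
        vals = np.transpose(f.values, perm)
        expand = [slice(None) if v in f.vars else np.newaxis for v in all_vars]
        out = out * vals[tuple(e for e in expand)]
    return _Factor(tuple(all_vars), out)


def _sum_out(factor: _Factor, var: str) -> _Factor:
    ax = factor.vars.index(var)
    return _Factor(tuple(v for v in factor.vars if v != var),
                   factor.values.sum(axis=ax))


def query_conditional(bn: DiscreteBN, target: str, evidence: dict | None = None
                      ) -> np.ndarray:
    """Exact ``P(target | evidence)`` by variable elimination.

    Evidence values may be category labels or integer level indices.
    Raises ``ValueError`` when the evidence configuration has probability
    zero under the network.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target cannot appear in evidence")
    ev_idx = {v: bn.level_index(v, val) for v, val in evidence.items()}

    factors: list[_Factor] = []
    for v in bn.dag.nodes:
        vars_ = bn.dag.parents(v) + (v,)
        vals = bn.cpts[v]
        # slice out evidence
        keep_vars, slicer = [], []
        for name in vars_:
            if name in ev_idx:
                slicer.append(ev_idx[name])
            else:
                keep_vars.append(name)
                slicer.append(slice(None))
        vals = vals[tuple(slicer)]
        factors.append(_Factor(tuple(keep_vars), np.asarray(vals, dtype=float)))

    # eliminate all hidden variables, cheapest (min resulting size) first
    hidden = [v for v in bn.dag.nodes if v != target and v not in ev_idx]
    while hidden:
        best_v, best_cost = None, None
        for v in hidden:
            involved = [f for f in factors if v in f.vars]
            vs = set()
            for f in involved:
                vs.update(f.vars)
            cost = float(np.prod([bn.card(w) for w in vs if w != v] or [1.0]))
            if best_cost is None or cost < best_cost or (
                    cost == best_cost and v < best_v):
                best_v, best_cost = v, cost
        involved = [f for f in factors if best_v in f.vars]
        rest = [f for f in factors if best_v not in f.vars]
        factors = rest + [_sum_out(_multiply(involved), best_v)]
        hidden.remove(best_v)

    joint = _multiply(factors)
    if joint.vars != (target,):
        perm = sorted(range(len(joint.vars)), key=lambda i: joint.vars[i] != target)
        joint = _Factor((target,), np.transpose(joint.values, perm).reshape(bn.card(target)))
    total = joint.values.sum()
    if total <= 0:
        raise ValueError(f"evidence configuration {evidence!r} has probability zero")
    return joint.values / total


def forward_sample(bn: DiscreteBN, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw ``n`` joint samples by ancestral (topological-order) sampling."""
    order = bn.dag.topological_order()
    out: dict[str, np.ndarray] = {}
    for v in order:
        ps = bn.dag.parents(v)
        cpt = bn.cpts[v]
        if not ps:
            probs = np.broadcast_to(cpt, (n, cpt.shape[-1]))
        else:
            idx = tuple(out[p] for p in ps)
            probs = cpt[idx]
        u = rng.random(n)
        out[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Import / export
# ---------------------------------------------------------------------------

def write_sif(edges, path, interaction: str = "->", confidence: dict | None = None
              ) -> None:
    """Write edges as SIF (``source <TAB> interaction <TAB> target``)."""
    with open(str(path), "w") as fh:
        for u, v in sorted(edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
    if confidence is not None:
        with open(str(path) + ".conf.tsv", "w") as fh:
            fh.write("source\ttarget\tconfidence\n")
            for (u, v), c in sorted(confidence.items()):
                fh.write(f"{u}\t{v}\t{c:.6g}\n")


def read_sif(path, nodes=None) -> DAG:
    edges = []
    seen = set()
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, _inter, v = line.split("\t")
            edges.append((u, v))
            seen.update((u, v))
    node_list = list(nodes) if nodes is not None else sorted(seen)
    return DAG(node_list, edges)


def read_graphml(path) -> DAG:
    """Import a DAG from GraphML (node id = variable name)."""
    import networkx as nx

    g = nx.read_graphml(str(path))
    return DAG(sorted(g.nodes), list(g.edges))


def write_graphml(dag: DAG, path, confidence: dict | None = None) -> None:
    """Export via networkx as GraphML with an optional edge 'confidence'."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    for u, v in sorted(dag.edges):
        attrs = {}
        if confidence is not None:
            c = confidence.get((u, v), confidence.get(frozenset((u, v))))
            if c is not None:
                attrs["confidence"] = float(c)
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, str(path))
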