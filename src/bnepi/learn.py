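"""Structure learning: hill climbing, IAMB, and MMHC.

Three learners over discrete data, sharing the scoring and testing
primitives in :mod:`bnepi.bn`:

* :func:`hill_climb` — greedy score-based search (add / delete / reverse
  moves, decomposable AIC, empty starting graph, no restarts);
* :func:`iamb` — the Incremental Association Markov Blanket algorithm
  (constraint-based: blanket discovery with the G² test, symmetry
  correction, neighbour determination, collider orientation);
* :func:`mmhc` — the hybrid Min-Max Hill-Climbing algorithm (MMPC skeleton
  with the max-min heuristic, then hill climbing restricted to the
  skeleton).

All tie-breaking is lexicographic in (source, target) variable names so a
run is bit-reproducible; robustness against search-order artifacts is
provided downstream by bootstrap model averaging, not by restarts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .bn import (DAG, CITestResult, ScoreCache, encode_strata, g2_statistic,
                 mi_ci_test)

log = logging.getLogger(__name__)

__all__ = ["hill_climb", "iamb", "mmhc", "SearchTrace", "LearnConfig"]

#: Significance level for the conditional-independence tests.
DEFAULT_ALPHA = 0.05
#: Largest conditioning set the G² test is attempted on; with quartile
#: variables at epidemiological sample sizes, larger strata are too sparse
#: for the asymptotic test to retain power.  A test whose conditioning set
#: exceeds the cap is skipped and dependence is assumed.
DEFAULT_MAX_COND = 3


@dataclass
class LearnConfig:
    alpha: float = DEFAULT_ALPHA
    max_cond: int = DEFAULT_MAX_COND


@dataclass
class SearchTrace:
    """Accepted hill-climbing moves, in order, and the final score."""
    steps: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    final_score: float = 0.0


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

def hill_climb(codes, cards, names, score_cache: ScoreCache | None = None,
               restrict: set[frozenset] | None = None,
               ) -> tuple[DAG, SearchTrace]:
    """Greedy AIC hill climbing from the empty graph.

    At each step the single best strictly-improving move among all edge
    additions, deletions and reversals is applied; ties are broken
    lexicographically by (move type, source, target).  ``restrict``, when
    given, limits additions (and hence the reachable edge set) to pairs
    whose undirected version is listed — used by MMHC phase 2.

    Returns the local optimum and the trace of accepted moves (every
    accepted delta is strictly positive, so the score is strictly
    increasing along the trace).
    """
    cache = score_cache or ScoreCache(codes, cards, names)
    names = cache.names
    p = len(names)
    idx = cache.index
    dag = DAG(names)

    def fam(v: str, parents: tuple[str, ...]) -> float:
        return cache.family_score(idx[v], tuple(idx[q] for q in parents))

    current = {v: fam(v, ()) for v in names}

    def allowed(u: str, v: str) -> bool:
        return restrict is None or frozenset((u, v)) in restrict

    # gain caches: gain_add[(u, v)] for u not parent of v, gain_del for edges
    gain_add: dict[tuple[str, str], float] = {}
    gain_del: dict[tuple[str, str], float] = {}

    def refresh_child(v: str) -> None:
        ps = dag.parents(v)
        for u in names:
            if u == v:
                continue
            if dag.has_edge(u, v):
                gain_add.pop((u, v), None)
                gain_del[(u, v)] = fam(v, tuple(q for q in ps if q != u)) - current[v]
            else:
                gain_del.pop((u, v), None)
                if allowed(u, v):
                    gain_add[(u, v)] = fam(v, tuple(sorted(ps + (u,)))) - current[v]

    for v in names:
        refresh_child(v)

    trace = SearchTrace()
    eps = 1e-9
    while True:
        candidates: list[tuple[float, int, str, str]] = []
        for (u, v), g in gain_add.items():
            if g > eps:
                candidates.append((g, 0, u, v))
        for (u, v), g in gain_del.items():
            if g > eps:
                candidates.append((g, 1, u, v))
        for (u, v) in list(gain_del.keys()):
            # reverse u->v  =  delete u->v  +  add v->u
            ga = gain_add.get((v, u))
            if ga is None:
                continue
            g = gain_del[(u, v)] + ga
            if g > eps:
                candidates.append((g, 2, u, v))
        # best strictly-improving move; lexicographic tie-break
        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        applied = False
        for g, kind, u, v in candidates:
            if kind == 0:
                if dag.has_path(v, u):
                    continue  # would create a cycle
                dag.add_edge(u, v)
                current[v] += gain_add[(u, v)]
                trace.steps.append(("add", (u, v), g))
                refresh_child(v)
            elif kind == 1:
                dag.remove_edge(u, v)
                current[v] += gain_del[(u, v)]
                trace.steps.append(("delete", (u, v), g))
                refresh_child(v)
            else:
                dag.remove_edge(u, v)
                if dag.has_path(u, v):
                    dag.add_edge(u, v)  # reversal would create a cycle
                    continue
                current[v] += gain_del[(u, v)]
                dag.add_edge(v, u)
                current[u] += gain_add[(v, u)]
                trace.steps.append(("reverse", (u, v), g))
                refresh_child(u)
                refresh_child(v)
            applied = True
            break
        if not applied:
            break

    trace.final_score = sum(current.values())
    return dag, trace


# ---------------------------------------------------------------------------
# Shared constraint-based helpers
# ---------------------------------------------------------------------------

def _test(codes, cards, x, y, zs, cfg: LearnConfig) -> CITestResult | None:
    """G² test, or None (dependence assumed) when |zs| exceeds the cap."""
    if len(zs) > cfg.max_cond:
        log.debug("CI test skipped: conditioning set size %d exceeds cap %d",
                  len(zs), cfg.max_cond)
        return None
    return mi_ci_test(codes, cards, x, y, tuple(zs))


def _find_sepset(codes, cards, x: int, y: int, pool: list[int], cfg: LearnConfig
                 ) -> tuple[int, ...] | None:
    """Smallest subset of ``pool`` (size <= cap) separating x and y, or None."""
    cx, cy = int(cards[x]), int(cards[y])
    for size in range(0, min(len(pool), cfg.max_cond) + 1):
        for s in itertools.combinations(sorted(pool), size):
            zcode, nz = encode_strata(codes, cards, s)
            _g2, _df, p = g2_statistic(codes[:, x], codes[:, y], cx, cy,
                                       zcode, nz)
            if p > cfg.alpha:
                return s
    return None


def _orient(names: list[str], adjacency: set[frozenset],
            sepsets: dict[frozenset, tuple[int, ...]],
            index: dict[str, int]) -> DAG:
    """Collider orientation + Meek propagation + deterministic completion."""
    directed: set[tuple[str, str]] = set()
    undirected = {frozenset(e) for e in adjacency}

    def adj(v: str) -> set[str]:
        out = set()
        for e in adjacency:
            if v in e:
                out.update(e - {v})
        return out

    # v-structures: x - z - y with x, y non-adjacent and z not in sepset(x, y)
    for z in sorted(names):
        nbrs = sorted(adj(z))
        for x, y in itertools.combinations(nbrs, 2):
            if frozenset((x, y)) in adjacency:
                continue
            sep = sepsets.get(frozenset((x, y)))
            if sep is not None and index[z] not in sep:
                for a in (x, y):
                    if (z, a) not in directed:
                        directed.add((a, z))
                    undirected.discard(frozenset((a, z)))

    def _path(edges, a, b):
        adjm: dict[str, list[str]] = {}
        for x, y in edges:
            adjm.setdefault(x, []).append(y)
        stack, seen = [a], {a}
        while stack:
            w = stack.pop()
            if w == b:
                return True
            for c in adjm.get(w, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def creates_cycle(u, v):
        return _path(directed, v, u)

    # Meek rule 1 (avoid new colliders) then deterministic completion
    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                # rule: if w -> u and w, v non-adjacent, orient u -> v
                for w, t in list(directed):
                    if t == u and frozenset((w, v)) not in adjacency and w != v:
                        if not creates_cycle(u, v):
                            directed.add((u, v))
                            undirected.discard(e)
                            changed = True
                        break
                if e not in undirected:
                    break
            if changed:
                break

    for e in sorted(undirected, key=sorted):
        a, b = sorted(e)
        if not creates_cycle(a, b):
            directed.add((a, b))
        else:
            directed.add((b, a))

    # conflicting v-structures can, rarely, leave a directed cycle; resolve
    # deterministically by dropping edges that would close one
    dag = DAG(names)
    for u, v in sorted(directed):
        if not dag.has_path(v, u):
            dag.add_edge(u, v)
        else:
            log.info("orientation conflict: dropping %s->%s", u, v)
    return dag


# ---------------------------------------------------------------------------
# IAMB
# ---------------------------------------------------------------------------

def iamb(codes, cards, names, alpha: float = DEFAULT_ALPHA,
         max_cond: int = DEFAULT_MAX_COND) -> DAG:
    """Incremental Association Markov Blanket learning.

    Forward phase: repeatedly add the variable with the largest G²
    association with the target conditional on the current blanket, provided
    the test rejects independence at ``alpha`` (skipped tests — conditioning
    set over the cap — never trigger an addition).  Backward phase: remove
    blanket members rendered independent given the rest.  Blankets are then
    symmetrized (AND rule), neighbours determined by sepset search within
    blankets, and edges oriented by the collider rule with deterministic
    completion.
    """
    cfg = LearnConfig(alpha=alpha, max_cond=max_cond)
    codes = np.asarray(codes)
    p = len(names)
    index = {n: i for i, n in enumerate(names)}

    blankets: dict[int, set[int]] = {}
    for t in range(p):
        mb: set[int] = set()
        tcol = codes[:, t]
        ct = int(cards[t])
        # forward
        while True:
            best, best_stat = None, 0.0
            zs = tuple(sorted(mb))
            if len(zs) > cfg.max_cond:
                log.debug("IAMB forward stopped: blanket of %d exceeds the "
                          "conditioning cap %d", len(zs), cfg.max_cond)
                break
            zcode, nz = encode_strata(codes, cards, zs)
            for x in range(p):
                if x == t or x in mb:
                    continue
                g2, _df, pv = g2_statistic(codes[:, x], tcol, int(cards[x]),
                                           ct, zcode, nz)
                if pv <= cfg.alpha and g2 > best_stat:
                    best, best_stat = x, g2
            if best is None:
                break
            mb.add(best)
            # backward: re-test every member given the rest of the blanket
            removed = True
            while removed:
                removed = False
                for x in sorted(mb):
                    rest = tuple(sorted(mb - {x}))
                    res = _test(codes, cards, x, t, rest, cfg)
                    if res is not None and res.p > cfg.alpha:
                        mb.discard(x)
                        removed = True
        blankets[t] = mb

    # symmetry correction (AND rule)
    for t in range(p):
        blankets[t] = {x for x in blankets[t] if t in blankets[x]}

    # neighbour determination within blankets
    adjacency: set[frozenset] = set()
    sepsets: dict[frozenset, tuple[int, ...]] = {}
    for t in range(p):
        for x in sorted(blankets[t]):
            if x < t:
                continue
            pool_t = sorted(blankets[t] - {x})
            pool_x = sorted(blankets[x] - {t})
            pool = pool_t if len(pool_t) <= len(pool_x) else pool_x
            sep = _find_sepset(codes, cards, t, x, pool, cfg)
            if sep is None:
                adjacency.add(frozenset((names[t], names[x])))
            else:
                sepsets[frozenset((names[t], names[x]))] = sep

    return _orient(list(names), adjacency, sepsets, index)


# ---------------------------------------------------------------------------
# MMHC
# ---------------------------------------------------------------------------

def _mmpc_one(codes, cards, t: int, p: int, cfg: LearnConfig) -> set[int]:
    """Candidate parent/child set of target ``t`` by the max-min heuristic.

    Candidates found independent of the target given any tested subset are
    excluded permanently, and after a CPC addition only subsets containing
    the newest member need testing — the two standard prunings that keep
    the subset enumeration tractable.
    """
    cpc: list[int] = []
    # per-candidate maximum p-value over the CPC subsets tested so far
    maxp: dict[int, float] = {x: 0.0 for x in range(p) if x != t}
    last_added: int | None = None
    tcol = codes[:, t]
    ct = int(cards[t])
    while maxp:
        others = [c for c in cpc if c != last_added]
        if last_added is None:
            subsets = [()]
        else:
            subsets = [tuple(sorted(s + (last_added,)))
                       for size in range(0, min(len(others), cfg.max_cond - 1) + 1)
                       for s in itertools.combinations(sorted(others), size)]
        for s in subsets:
            zcode, nz = encode_strata(codes, cards, s)
            for x in list(maxp):
                _g2, _df, pv = g2_statistic(codes[:, x], tcol, int(cards[x]),
                                            ct, zcode, nz)
                if pv > maxp[x]:
                    maxp[x] = pv
                if pv > cfg.alpha:
                    del maxp[x]  # independent: excluded permanently
            if not maxp:
                break
        if not maxp:
            break
        # max-min: the candidate whose weakest association is strongest
        best = min(sorted(maxp), key=lambda x: maxp[x])
        cpc.append(best)
        del maxp[best]
        last_added = best
    # backward pruning
    keep = list(cpc)
    for x in list(keep):
        pool = sorted(set(keep) - {x})
        if _find_sepset(codes, cards, x, t, pool, cfg) is not None:
            keep.remove(x)
    return set(keep)


def mmhc(codes, cards, names, alpha: float = DEFAULT_ALPHA,
         max_cond: int = DEFAULT_MAX_COND) -> DAG:
    """Min-Max Hill-Climbing: MMPC skeleton, then restricted hill climbing."""
    cfg = LearnConfig(alpha=alpha, max_cond=max_cond)
    codes = np.asarray(codes)
    p = len(names)
    cpcs = {t: _mmpc_one(codes, cards, t, p, cfg) for t in range(p)}
    # symmetry (AND rule)
    skeleton: set[frozenset] = set()
    for t in range(p):
        for x in cpcs[t]:
            if t in cpcs[x]:
                skeleton.add(frozenset((names[t], names[x])))
    dag, _trace = hill_climb(codes, cards, names, restrict=skeleton)
    return dag
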