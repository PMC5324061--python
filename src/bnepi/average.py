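"""Bootstrap model averaging of learned network structures.

A single structure-learning run on epidemiological data is fragile; the
averaged-network approach learns one DAG per nonparametric bootstrap
resample of subjects, tabulates for every variable pair the *edge
confidence* — the frequency with which the pair is connected (in either
direction) across the replicates — and keeps the pairs whose confidence
exceeds a threshold estimated from the observed confidence distribution
itself.

The threshold estimator treats the empirical CDF of the confidences as a
noisy version of an ideal two-level CDF in which noise edges have
confidence 0 and true edges confidence 1, and picks the cut minimizing the
L1 distance between the two; the search is exhaustive over the observed
confidence values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import DAG, ScoreCache
from . import learn as _learn

log = logging.getLogger(__name__)

__all__ = [
    "EdgeConfidenceTable",
    "AveragedNetwork",
    "bootstrap_confidences",
    "estimate_threshold",
    "averaged_network",
    "multi_algorithm_consensus",
]

ALGORITHMS = ("hc", "iamb", "mmhc")


@dataclass
class EdgeConfidenceTable:
    """Per-pair bootstrap frequencies from one algorithm's replicates."""
    nodes: list[str]
    undirected: dict[frozenset, float]      # confidence of the relation
    directed: dict[tuple[str, str], float]  # directional frequencies
    B: int
    threshold: float | None = None

    def confidence(self, u: str, v: str) -> float:
        return self.undirected.get(frozenset((u, v)), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        thr = self.threshold
        for pair in sorted(self.undirected, key=sorted):
            a, b = sorted(pair)
            rows.append({
                "source": a, "target": b,
                "freq_forward": self.directed.get((a, b), 0.0),
                "freq_backward": self.directed.get((b, a), 0.0),
                "confidence": self.undirected[pair],
                "included": (thr is not None
                             and self.undirected[pair] > thr),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(str(path), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, B: int = 0) -> "EdgeConfidenceTable":
        df = pd.read_csv(str(path), sep="\t")
        und, dire, nodes = {}, {}, set()
        for row in df.itertuples(index=False):
            a, b = str(row.source), str(row.target)
            nodes.update((a, b))
            und[frozenset((a, b))] = float(row.confidence)
            if row.freq_forward:
                dire[(a, b)] = float(row.freq_forward)
            if row.freq_backward:
                dire[(b, a)] = float(row.freq_backward)
        return cls(nodes=sorted(nodes), undirected=und, directed=dire, B=B)


def _learn_one(algorithm: str, codes, cards, names, alpha, max_cond) -> DAG:
    if algorithm == "hc":
        dag, _ = _learn.hill_climb(codes, cards, names)
        return dag
    if algorithm == "iamb":
        return _learn.iamb(codes, cards, names, alpha=alpha, max_cond=max_cond)
    if algorithm == "mmhc":
        return _learn.mmhc(codes, cards, names, alpha=alpha, max_cond=max_cond)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def bootstrap_confidences(codes, cards, names, algorithm: str = "hc",
                          B: int = 1000, seed=None,
                          alpha: float = _learn.DEFAULT_ALPHA,
                          max_cond: int = _learn.DEFAULT_MAX_COND,
                          ) -> EdgeConfidenceTable:
    """Edge confidences from ``B`` bootstrap-resampled structure learnings.

    The resampling unit is the subject (row).  A replicate in which a
    variable becomes constant is handled gracefully: the learners see a
    single-category variable and leave it isolated (logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = np.asarray(codes)
    n = codes.shape[0]
    und: dict[frozenset, float] = {}
    dire: dict[tuple[str, str], float] = {}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = codes[idx]
        for j in range(sample.shape[1]):
            if np.all(sample[:, j] == sample[0, j]):
                log.info("replicate %d: variable %s constant in resample",
                         b, names[j])
        dag = _learn_one(algorithm, sample, cards, names, alpha, max_cond)
        for u, v in dag.edges:
            und[frozenset((u, v))] = und.get(frozenset((u, v)), 0.0) + 1.0
            dire[(u, v)] = dire.get((u, v), 0.0) + 1.0
    for k in und:
        und[k] /= B
    for k in dire:
        dire[k] /= B
    return EdgeConfidenceTable(nodes=list(names), undirected=und,
                               directed=dire, B=B)


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

def _l1_to_two_level(sorted_conf: np.ndarray, pi0: float) -> float:
    """L1 distance on [0, 1] between the ECDF of the confidences and the
    ideal CDF that jumps to ``pi0`` at 0 and to 1 at 1 (mass ``pi0`` of
    noise edges at confidence 0, the rest at 1)."""
    x = np.concatenate([[0.0], sorted_conf, [1.0]])
    n = sorted_conf.size
    ecdf = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    widths = np.diff(x)
    # ECDF value on [x_i, x_{i+1}) is ecdf[i]
    return float(np.sum(np.abs(ecdf[:-1] - pi0) * widths))


def estimate_threshold(confidences) -> float:
    """Inclusion cut estimated from the confidence distribution.

    For every observed confidence value ``t`` as candidate cut, edges with
    confidence <= t are treated as noise (ideal confidence 0) and the rest
    as true edges (ideal confidence 1); the returned threshold minimizes
    the L1 distance between the empirical CDF and that two-level ideal,
    with the cut placed midway between the two separated confidence classes
    for numeric headroom.
    """
    conf = np.sort(np.asarray(list(confidences), float))
    if conf.size < 2 or np.allclose(conf, conf[0]):
        raise ValueError("threshold undefined: all confidence values equal")
    n = conf.size
    best_t, best_l1 = None, np.inf
    candidates = np.unique(conf)
    for t in candidates:
        pi0 = float(np.mean(conf <= t))
        l1 = _l1_to_two_level(conf, pi0)
        if l1 < best_l1 - 1e-15:
            best_l1, best_t = l1, t
    above = conf[conf > best_t]
    upper = float(above.min()) if above.size else 1.0
    thr = 0.5 * (float(best_t) + upper)
    return min(max(thr, 1e-9), 1 - 1e-9)


# ---------------------------------------------------------------------------
# Averaged network
# ---------------------------------------------------------------------------

@dataclass
class AveragedNetwork:
    """Consensus DAG with per-edge bootstrap confidence."""
    dag: DAG
    confidence: dict[tuple[str, str], float]
    threshold: float
    tied_directions: list[tuple[str, str]] = field(default_factory=list)
    removed_in_repair: list[tuple[str, str]] = field(default_factory=list)
    reoriented_in_repair: list[tuple[str, str]] = field(default_factory=list)


def averaged_network(conf: EdgeConfidenceTable,
                     threshold: float | None = None) -> AveragedNetwork:
    """Build the averaged network from an edge-confidence table.

    Pairs with confidence strictly above the threshold are included; each
    kept pair is oriented along its majority directional frequency (ties
    broken lexicographically and flagged).  If the majority orientations
    form a directed cycle, the lowest-confidence edge in each cycle is
    deleted (logged) so the result is a DAG.
    """
    if threshold is None:
        threshold = conf.threshold
        if threshold is None:
            threshold = estimate_threshold(list(conf.undirected.values()))
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")

    chosen: list[tuple[str, str, float]] = []
    tied = []
    for pair, c in sorted(conf.undirected.items(), key=lambda kv: sorted(kv[0])):
        if c <= threshold:
            continue
        a, b = sorted(pair)
        f_ab = conf.directed.get((a, b), 0.0)
        f_ba = conf.directed.get((b, a), 0.0)
        if f_ab == f_ba:
            tied.append((a, b))
            u, v = a, b
        elif f_ab > f_ba:
            u, v = a, b
        else:
            u, v = b, a
        chosen.append((u, v, c))

    # cycle repair: insert edges from highest confidence down, dropping any
    # edge that would close a cycle (equivalently: delete the weakest edge
    # of each cycle)
    removed = []
    reoriented = []
    dag = DAG(conf.nodes)
    kept: list[tuple[str, str, float]] = []
    for u, v, c in sorted(chosen, key=lambda t: (-t[2], t[0], t[1])):
        if not dag.has_path(v, u):
            dag.add_edge(u, v)
            kept.append((u, v, c))
        elif not dag.has_path(u, v):
            # the relation survives with its minority orientation
            dag.add_edge(v, u)
            kept.append((v, u, c))
            reoriented.append((u, v))
            log.info("cycle repair: reorienting %s->%s (confidence %.3f)",
                     u, v, c)
        else:
            removed.append((u, v))
            log.warning("cycle repair: dropping %s-%s (confidence %.3f)",
                        u, v, c)
    confidence = {(u, v): c for u, v, c in kept}
    return AveragedNetwork(dag=dag, confidence=confidence,
                           threshold=float(threshold), tied_directions=tied,
                           removed_in_repair=removed,
                           reoriented_in_repair=reoriented)


def multi_algorithm_consensus(networks: dict[str, AveragedNetwork],
                              tables: dict[str, EdgeConfidenceTable] | None = None
                              ) -> pd.DataFrame:
    """Annotate the union of averaged networks with per-algorithm support.

    One row per undirected edge present in at least one algorithm's
    averaged network, listing the supporting algorithms and each
    algorithm's confidence for the pair (from its confidence table when
    provided, else from its averaged network).
    """
    if len(networks) < 2:
        raise ValueError("consensus needs at least two algorithms")
    support: dict[frozenset, list[str]] = {}
    for alg, net in networks.items():
        for (u, v) in net.dag.edges:
            support.setdefault(frozenset((u, v)), []).append(alg)
    rows = []
    for pair in sorted(support, key=sorted):
        a, b = sorted(pair)
        row = {"source": a, "target": b,
               "supported_by": ",".join(sorted(support[pair])),
               "n_algorithms": len(support[pair])}
        for alg in sorted(networks):
            if tables is not None and alg in tables:
                row[f"confidence_{alg}"] = tables[alg].confidence(a, b)
            else:
                c = networks[alg].confidence
                row[f"confidence_{alg}"] = c.get((a, b), c.get((b, a), 0.0))
        rows.append(row)
    return pd.DataFrame(rows)
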