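"""Odds ratios and risk summaries from a fitted discrete network.

Given a network with conditional probability tables, the odds ratio
comparing an exposure assignment E to a reference assignment R is

    OR = [P(case | E) / P(control | E)] / [P(case | R) / P(control | R)]

with the conditional probabilities computed by exact variable elimination
rather than stochastic sampling — the same estimand as simulation-based
conditional-probability queries, evaluated deterministically.  Adjustment
for design (matching) variables is done by standardization: the
outcome probability under each exposure is averaged over the empirical
joint distribution of the matching variables among controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn import DiscreteBN, query_conditional
from .cohort import CohortTable

log = logging.getLogger(__name__)

__all__ = ["or_from_bn", "or_grid", "ORGrid"]


def _case_index(bn: DiscreteBN, outcome: str) -> int:
    levels = bn.levels[outcome]
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, has {levels}")
    for lab in ("1", "case", "True"):
        if lab in levels:
            return levels.index(lab)
    return 1


def _p_case(bn: DiscreteBN, outcome: str, assignment: dict,
            conditioning_weights: list[tuple[dict, float]] | None) -> float:
    ci = _case_index(bn, outcome)
    if not conditioning_weights:
        return float(query_conditional(bn, outcome, assignment)[ci])
    total, acc = 0.0, 0.0
    for combo, w in conditioning_weights:
        ev = {**assignment, **combo}
        try:
            p = float(query_conditional(bn, outcome, ev)[ci])
        except ValueError:
            continue  # zero-probability stratum: no mass to standardize over
        acc += w * p
        total += w
    if total <= 0:
        raise ValueError("no conditioning stratum has positive probability")
    return acc / total


def or_from_bn(bn: DiscreteBN, outcome: str, exposure_assignment: dict,
               reference_assignment: dict,
               conditioning: list[tuple[dict, float]] | None = None) -> float:
    """Odds ratio between two exposure assignments from exact inference.

    ``conditioning`` is an optional list of (assignment, weight) pairs —
    typically the empirical joint distribution of the matching variables
    among controls — over which the outcome probability is standardized
    before forming the odds.  Identical exposure and reference assignments
    give OR = 1 exactly.
    """
    if exposure_assignment == reference_assignment:
        return 1.0
    p1 = _p_case(bn, outcome, exposure_assignment, conditioning)
    p0 = _p_case(bn, outcome, reference_assignment, conditioning)
    for name, p in (("exposure", p1), ("reference", p0)):
        if p <= 0.0 or p >= 1.0:
            raise ValueError(
                f"outcome probability under the {name} assignment is {p}; "
                f"refit the CPTs with smoothing > 0 to avoid zero cells")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def control_distribution(table: CohortTable, variables: list[str]
                         ) -> list[tuple[dict, float]]:
    """Empirical joint distribution of ``variables`` among controls,
    as (assignment, weight) pairs for standardization."""
    ctrl = table.data.loc[~np.asarray(table.case_mask)]
    counts = ctrl.groupby(variables, observed=True).size()
    total = counts.sum()
    out = []
    for combo, c in counts.items():
        combo = combo if isinstance(combo, tuple) else (combo,)
        out.append(({v: str(val) for v, val in zip(variables, combo)},
                    c / total))
    return out


@dataclass
class ORGrid:
    """Joint exposure-category table with counts and BN odds ratios."""
    exposures: list[str]
    reference: dict
    frame: pd.DataFrame  # one row per category combination

    def to_tsv(self, path) -> None:
        self.frame.to_csv(str(path), sep="\t", index=False)


def or_grid(bn: DiscreteBN, table: CohortTable, exposures: list[str],
            adjust_for_matching: bool = True) -> ORGrid:
    """BN odds ratios for every category combination of the exposures.

    The joint lowest-category cell is the reference (OR printed as
    ``ref``); cell counts (cases/controls) come from the analysis table;
    ORs are standardized over the control distribution of the matching
    variables when ``adjust_for_matching`` is set.  Empty cells keep their
    zero count and are flagged; their OR still exists because the CPTs are
    smoothed.
    """
    for e in exposures:
        if e not in bn.dag.nodes:
            raise ValueError(f"exposure {e!r} not in the network")
    outcome = table.outcome
    matching = table.variables("matching") if adjust_for_matching else []
    matching = [v for v in matching if v in bn.dag.nodes]
    cond = control_distribution(table, matching) if matching else None

    levels = {e: table.categories(e) for e in exposures}
    reference = {e: levels[e][0] for e in exposures}
    case = np.asarray(table.case_mask)

    rows = []
    combos = [()]
    for e in exposures:
        combos = [c + (lv,) for c in combos for lv in levels[e]]
    for combo in combos:
        assignment = dict(zip(exposures, combo))
        mask = np.ones(len(table.data), dtype=bool)
        for e, lv in assignment.items():
            mask &= (table.data[e].astype(str) == lv).to_numpy()
        n_case = int((mask & case).sum())
        n_ctrl = int((mask & ~case).sum())
        is_ref = assignment == reference
        orv = (1.0 if is_ref else
               or_from_bn(bn, outcome, assignment, reference, cond))
        rows.append({**{e: assignment[e] for e in exposures},
                     "cases": n_case, "controls": n_ctrl,
                     "or_bn": orv,
                     "or_bn_label": "ref" if is_ref else f"{orv:.2f}",
                     "empty_cell": n_case + n_ctrl == 0})
        if n_case + n_ctrl == 0:
            log.warning("empty cell %s: OR from smoothed CPTs", assignment)
    return ORGrid(exposures=list(exposures), reference=reference,
                  frame=pd.DataFrame(rows))
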