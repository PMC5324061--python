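"""Config-driven end-to-end runs.

One :func:`run_pipeline` call executes the whole analysis on a synthetic
cohort: generate -> discretize -> learn (bootstrap, per algorithm) ->
average -> consensus -> BN odds-ratio grid -> matched regression suite,
writing every artifact as plain text into the run directory together with
a machine-readable manifest (name, path, sha256).  Runs are deterministic
given the seed.  Subgroup re-runs (by sex) and sensitivity re-runs
(septile discretization, fasting-subset exclusion) reuse the same base
cohort so their tables partition or subset it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import average as avg
from . import epi, inference, learn, prep
from .bn import fit_cpts, write_sif
from .cohort import CohortTable
from .simulate import TruthSpec, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "apply_exclusion"]


@dataclass
class RunConfig:
    """Knobs for one pipeline run.

    ``k`` is the metabolite discretization depth (4 = quartiles for the
    main analysis, 3 = tertiles for interaction grids, 7 = septiles for the
    sensitivity run).  ``exclusions`` names row filters applied before
    analysis; subjects excluded drag their matched sets' integrity along
    (a set losing its case, or all controls, is dropped entirely).
    """
    seed: int = 0
    n_cases: int = 613
    controls_per_case: int = 2
    k: int = 4
    grid_k: int = 3
    B: int = 100
    algorithms: tuple[str, ...] = ("hc", "iamb", "mmhc")
    alpha: float = 0.05
    max_cond: int = 3
    exclusions: tuple[str, ...] = ()
    subgroups: tuple[str, ...] = ()
    sensitivity: tuple[str, ...] = ()
    grid_exposures: tuple[str, str] = ("vitamin_B2", "vitamin_B6")
    out_dir: str = "bnepi_run"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        unknown = set(self.algorithms) - set(avg.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("algorithms", "exclusions", "subgroups", "sensitivity",
                    "grid_exposures"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def apply_exclusion(table: CohortTable, rule: str) -> CohortTable:
    """Named row filters; matched controls follow their excluded case.

    ``fasting_lt4h`` removes subjects sampled after fasting less than four
    hours.  After filtering, sets left without their case or without any
    control are removed so every remaining set is analyzable.
    """
    if rule == "fasting_lt4h":
        keep = (table.data["fasting"].astype(str) != "<4h").to_numpy()
    else:
        raise ValueError(f"unknown exclusion rule {rule!r}")
    sub = table.subset(keep, drop_orphan_sets=True)
    # also drop sets left without any control
    case = np.asarray(sub.case_mask)
    sets = sub.data["matched_set_id"]
    with_ctrl = set(sets[~case])
    return sub.subset(sets.isin(with_ctrl).to_numpy(), drop_orphan_sets=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze(table: CohortTable, cfg: RunConfig, out: Path, tag: str,
             manifest: dict, rng: np.random.Generator) -> dict:
    """Learn, average and summarize one analysis table."""
    results: dict = {"tag": tag}
    codes, cards, names = table.encoded()
    tables, networks = {}, {}
    for alg in cfg.algorithms:
        conf = avg.bootstrap_confidences(
            codes, cards, names, algorithm=alg, B=cfg.B,
            seed=np.random.default_rng(rng.integers(2**31)),
            alpha=cfg.alpha, max_cond=cfg.max_cond)
        try:
            conf.threshold = avg.estimate_threshold(list(conf.undirected.values()))
        except ValueError:
            conf.threshold = 0.5
            log.warning("%s/%s: degenerate confidences, threshold fixed at 0.5",
                        tag, alg)
        net = avg.averaged_network(conf)
        tables[alg], networks[alg] = conf, net
        conf.to_tsv(out / f"{tag}_confidence_{alg}.tsv")
        write_sif(net.dag.edges, out / f"{tag}_network_{alg}.sif",
                  confidence=net.confidence)
        results[f"threshold_{alg}"] = conf.threshold
        results[f"edges_{alg}"] = len(net.dag.edges)
    if len(networks) >= 2:
        consensus = avg.multi_algorithm_consensus(networks, tables)
        consensus.to_csv(out / f"{tag}_consensus.tsv", sep="\t", index=False)
    results["thresholds"] = {a: tables[a].threshold for a in tables}
    return results


def run_pipeline(config: RunConfig, truth: TruthSpec | None = None) -> dict:
    """Execute the full pipeline; returns the results manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "artifacts": {}}
    rng = np.random.default_rng(config.seed)

    # ---- simulate --------------------------------------------------------
    spec = truth or TruthSpec(seed=config.seed)
    cohort = generate_cohort(spec, n_cases=config.n_cases,
                             controls_per_case=config.controls_per_case)
    cohort.table.to_tsv(out / "cohort.tsv")
    write_sif(cohort.truth_dag.edges, out / "truth.sif")
    log.info("simulated %d cases / %d controls (shortfall %d)",
             cohort.n_cases, cohort.n_controls, cohort.shortfall)

    # ---- prep ------------------------------------------------------------
    base = cohort.table
    for rule in config.exclusions:
        base = apply_exclusion(base, rule)
    table, cutoffs = prep.discretize_cohort(base, k=config.k)
    table.to_tsv(out / "analysis.tsv")
    report = prep.spearman_matrix(
        base.data[[c for c in base.data.columns if c.endswith("_conc")]]
        .rename(columns=lambda c: c[:-5]))
    report.to_tsv(out / "spearman.tsv")
    baseline = prep.baseline_comparison(
        table, base.data[[c for c in base.data.columns
                          if c.endswith("_conc")]])
    baseline.to_csv(out / "baseline_tests.tsv", sep="\t", index=False)

    # ---- learn / average / consensus ------------------------------------
    results = {"main": _analyze(table, config, out, "main", manifest, rng)}

    # ---- BN odds-ratio grid (tertile discretization) ---------------------
    grid_table, _ = prep.discretize_cohort(base, k=config.grid_k)
    g_codes, g_cards, g_names = grid_table.encoded()
    hc_dag, _ = learn.hill_climb(g_codes, g_cards, g_names)
    bn_fit = fit_cpts(hc_dag, g_codes, g_cards, g_names, smoothing=0.5,
                      levels={v: grid_table.categories(v) for v in g_names})
    grid = inference.or_grid(bn_fit, grid_table,
                             list(config.grid_exposures))
    grid.to_tsv(out / "or_grid.tsv")
    results["or_grid"] = grid.frame.to_dict(orient="records")

    # ---- matched regression suite ----------------------------------------
    epi_res: dict = {}
    b2 = config.grid_exposures[0]
    p_trend, fit = epi.trend_test(table, b2)
    epi_res["trend"] = {"variable": b2, "p": p_trend,
                        "beta": float(fit.params.iloc[0])}
    p_int, coef = epi.interaction_test(table, *config.grid_exposures)
    epi_res["interaction"] = {"pair": list(config.grid_exposures),
                              "p": p_int, "coefficient": coef}
    rd = epi.marginal_rd(table, b2, spec.baseline_risk / 1e5,
                         strata=["sex", "cohort"], boot_B=100,
                         seed=np.random.default_rng(rng.integers(2**31)))
    epi_res["rd"] = {"reference": rd.reference,
                     "rd": rd.rd.to_dict(),
                     "ci_low": rd.ci_low.to_dict(),
                     "ci_high": rd.ci_high.to_dict()}
    results["epi"] = epi_res

    # ---- subgroup and sensitivity re-runs --------------------------------
    for sg in config.subgroups:
        for level in table.categories(sg):
            mask = (table.data[sg].astype(str) == level).to_numpy()
            sub = table.subset(mask)
            if sub.n_subjects == 0:
                continue
            results[f"subgroup_{sg}_{level}"] = _analyze(
                sub, config, out, f"subgroup_{sg}_{level}", manifest, rng)
    for sens in config.sensitivity:
        if sens == "septiles":
            sens_table, _ = prep.discretize_cohort(base, k=7)
        elif sens == "fasting_lt4h":
            sens_table, _ = prep.discretize_cohort(
                apply_exclusion(base, "fasting_lt4h"), k=config.k)
        else:
            raise ValueError(f"unknown sensitivity run {sens!r}")
        results[f"sensitivity_{sens}"] = _analyze(
            sens_table, config, out, f"sensitivity_{sens}", manifest, rng)

    manifest["results"] = results
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
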