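"""Synthetic matched case-control cohorts with a known ground-truth network.

The generator emulates the statistical structure of a nested case-control
study of one-carbon metabolism (1CM) and colorectal cancer (CRC):

* 14 plasma metabolites whose pairwise Spearman correlations follow the
  published cluster structure (choline pathway, B-vitamins, glycine/serine,
  transsulfuration) — realized through a linear Gaussian structural model
  on the latent scale followed by log-normal marginal transforms, so the
  rank correlations are exactly the latent Pearson correlations mapped
  through ``r_S = (6/pi)·asin(rho/2)``;
* 17 SNPs in Hardy-Weinberg equilibrium with within-gene linkage
  disequilibrium generated at the haplotype level;
* a genotype effect of the MTHFR 677C>T variant on homocysteine;
* a rare binary outcome from a logistic model driven by folate (direct),
  vitamin B6 (inverse) and vitamin B2 (inverse) with a B2 x B6 interaction;
* incidence-density-style matched sampling of controls (matched on sex,
  sampling-year group, fasting status, cohort, and age within a caliper).

Because every dependency is written down in :class:`TruthSpec`, the
generating equations define a ground-truth DAG against which learned
networks can be scored.

All randomness flows from a single integer seed: child streams for the
genotype, metabolite, outcome and matching stages are split off the master
``numpy.random.Generator`` via ``spawn`` so stages are independently
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bn import DAG
from .cohort import CohortTable

log = logging.getLogger(__name__)

__all__ = [
    "TruthSpec",
    "SyntheticCohort",
    "spearman_to_pearson",
    "generate_genotypes",
    "generate_metabolites",
    "generate_outcome_and_match",
    "generate_cohort",
    "simulate_matched_sets",
]

# ---------------------------------------------------------------------------
# Study-like constants
# ---------------------------------------------------------------------------

METABOLITES = [
    "folate", "vitamin_B6", "vitamin_B2", "vitamin_B12",
    "homocysteine", "cystathionine", "cysteine", "glycine", "serine",
    "methionine", "choline", "betaine", "DMG", "sarcosine",
]

#: Log-normal marginal parameters (mu, sigma of the log) per metabolite,
#: placed so medians and interquartile ranges resemble adult plasma values
#: (nmol/L for the B-vitamins and folate, umol/L otherwise).
LOGNORMAL_MARGINALS = {
    "folate": (math.log(7.2), 0.59),
    "vitamin_B6": (math.log(38.2), 0.45),
    "vitamin_B2": (math.log(11.8), 0.61),
    "vitamin_B12": (math.log(426.0), 0.26),
    "homocysteine": (math.log(9.9), 0.26),
    "cystathionine": (math.log(0.16), 0.45),
    "cysteine": (math.log(276.0), 0.12),
    "glycine": (math.log(225.0), 0.26),
    "serine": (math.log(110.0), 0.19),
    "methionine": (math.log(26.4), 0.18),
    "choline": (math.log(8.6), 0.19),
    "betaine": (math.log(30.8), 0.23),
    "DMG": (math.log(3.6), 0.28),
    "sarcosine": (math.log(1.5), 0.42),
}

#: 17 polymorphisms in 13 one-carbon-metabolism genes with plausible
#: European minor-allele frequencies (three deliberately rare, so the
#: genotype-collapsing rule downstream is exercised).
SNPS = [
    ("MTHFR_677CT", 0.32), ("MTHFR_1298AC", 0.31),
    ("CBS_844ins68", 0.047), ("CBS_699CT", 0.32),
    ("MTR_2756AG", 0.19),
    ("MTRR_66AG", 0.45), ("MTRR_524CT", 0.35),
    ("BHMT_742GA", 0.30),
    ("TCN2_67AG", 0.13), ("TCN2_776CG", 0.45),
    ("RFC1_80GA", 0.48), ("FOLR1_1413GA", 0.04),
    ("MTHFD1_1958GA", 0.44), ("CTH_1364GT", 0.30),
    ("SHMT1_1420CT", 0.30), ("DHFR_del19", 0.42), ("TYMS_del6", 0.30),
]

#: Within-gene linkage, (snp_i, snp_j, r^2); feasibility depends on MAFs.
LD_PAIRS = [
    ("MTHFR_677CT", "MTHFR_1298AC", 0.25),
    ("CBS_844ins68", "CBS_699CT", 0.08),
    ("MTRR_66AG", "MTRR_524CT", 0.30),
    ("TCN2_67AG", "TCN2_776CG", 0.15),
]

#: Latent linear-Gaussian structural edges (parent, child, path coefficient
#: on the standardized latent scale).  Coefficients are placed so the
#: implied marginal correlations of the directly related pairs match the
#: published Spearman values after the sin transform: glycine-serine 0.52,
#: choline-betaine 0.40, folate/homocysteine -0.37, B12/homocysteine -0.28,
#: choline-methionine at the top of the reported 0.17-0.28 band.
SEM_EDGES = [
    ("folate", "vitamin_B6", 0.35),
    ("vitamin_B6", "vitamin_B2", 0.35),
    ("folate", "vitamin_B12", 0.30),
    ("folate", "homocysteine", -0.330),
    ("vitamin_B12", "homocysteine", -0.194),
    ("serine", "glycine", 0.545),
    ("choline", "betaine", 0.419),
    ("betaine", "DMG", 0.45),
    ("DMG", "sarcosine", 0.35),
    ("choline", "methionine", 0.293),
    ("methionine", "cystathionine", 0.35),
    ("cystathionine", "cysteine", 0.35),
    ("homocysteine", "cysteine", 0.30),
]


def spearman_to_pearson(r_s):
    """Latent Pearson correlation hitting a Spearman target exactly
    under a Gaussian copula: ``rho = 2 sin(pi r_S / 6)``."""
    return 2.0 * np.sin(np.pi * np.asarray(r_s) / 6.0)


def pearson_to_spearman(rho):
    return (6.0 / np.pi) * np.arcsin(np.asarray(rho) / 2.0)


def _sem_correlation(names: list[str], edges) -> np.ndarray:
    """Implied correlation matrix of a standardized linear Gaussian SEM."""
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    parents: dict[int, list[tuple[int, float]]] = {i: [] for i in range(p)}
    for u, v, b in edges:
        parents[idx[v]].append((idx[u], float(b)))
    dag = DAG(names, [(u, v) for u, v, _ in edges])
    order = [idx[v] for v in dag.topological_order()]
    C = np.zeros((p, p))
    done: list[int] = []
    for j in order:
        pa = parents[j]
        if not pa:
            C[j, j] = 1.0
        else:
            pi = [q for q, _ in pa]
            b = np.array([w for _, w in pa])
            expl = float(b @ C[np.ix_(pi, pi)] @ b)
            if expl >= 1.0:
                raise ValueError(f"path coefficients into {names[j]} imply "
                                 f"explained variance {expl:.3f} >= 1")
            for k in done:
                C[j, k] = C[k, j] = float(b @ C[pi, k])
            C[j, j] = 1.0
        done.append(j)
    return C


# ---------------------------------------------------------------------------
# Truth specification
# ---------------------------------------------------------------------------

@dataclass
class TruthSpec:
    """Everything needed to generate a cohort and name its true network.

    ``outcome_log_or`` maps a metabolite name to the log odds ratio per SD
    of its latent (log-scale) concentration; ``interaction`` is one pairwise
    product term on the same scale.  ``genotype_metabolite_effects`` entries
    are (snp, metabolite, shift per minor allele in latent-SD units).
    ``baseline_risk`` is the cohort cumulative incidence in cases per
    100,000.
    """

    metabolites: list[str] = field(default_factory=lambda: list(METABOLITES))
    latent_corr: np.ndarray | None = None
    metabolite_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(SEM_EDGES))
    snp_names: list[str] = field(default_factory=lambda: [s for s, _ in SNPS])
    snp_mafs: list[float] = field(default_factory=lambda: [m for _, m in SNPS])
    ld_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(LD_PAIRS))
    genotype_metabolite_effects: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("MTHFR_677CT", "homocysteine", 0.50)])
    outcome_log_or: dict[str, float] = field(default_factory=lambda: {
        "folate": 0.7, "vitamin_B6": -0.7, "vitamin_B2": -0.7})
    interaction: tuple[str, str, float] | None = ("vitamin_B2", "vitamin_B6", 0.25)
    covariate_effects: list[tuple[str, str, str, float]] = field(
        default_factory=lambda: [("smoking", "current", "vitamin_B6", -0.50)])
    baseline_risk: float = 830.0  # cases per 100,000
    age_caliper: float = 2.0      # years; the matched-design age tolerance
    seed: int = 0

    def __post_init__(self) -> None:
        mafs = np.asarray(self.snp_mafs, float)
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if self.baseline_risk <= 0:
            raise ValueError("baseline_risk must be positive")
        if self.latent_corr is None:
            self.latent_corr = _sem_correlation(self.metabolites,
                                                self.metabolite_edges)
        self.latent_corr = np.asarray(self.latent_corr, float)
        w = np.linalg.eigvalsh(self.latent_corr)
        if w.min() < -1e-10:
            raise ValueError(
                f"latent correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3e})")

    # -- ground truth -------------------------------------------------------

    def truth_dag(self, extra_nodes: list[str] | None = None) -> DAG:
        """The DAG implied by the generating equations.

        Metabolite SEM edges, within-gene LD (represented as a directed
        edge), genotype-to-metabolite and covariate-to-metabolite effects,
        outcome drivers, and the design dependencies among background
        variables (cohort determines the sex mix and the fasting mix).
        """
        nodes = (list(self.metabolites) + list(self.snp_names) + ["crc"]
                 + ["sex", "cohort", "fasting", "year_group", "age_group",
                    "smoking"])
        for n in extra_nodes or []:
            if n not in nodes:
                nodes.append(n)
        edges: list[tuple[str, str]] = []
        edges += [(u, v) for u, v, _ in self.metabolite_edges]
        edges += [(a, b) for a, b, _ in self.ld_pairs]
        edges += [(s, m) for s, m, _ in self.genotype_metabolite_effects]
        edges += [(cov, m) for cov, _lvl, m, _b in self.covariate_effects]
        edges += [(v, "crc") for v in self.outcome_log_or if
                  self.outcome_log_or[v] != 0]
        edges += [("cohort", "sex"), ("cohort", "fasting")]
        return DAG(nodes, set(edges))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _haplotype_freqs(p1: float, p2: float, r2: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) for minor alleles A/B with
    the requested squared haplotype correlation."""
    r = math.sqrt(r2)
    d = r * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    freqs = np.array([
        p1 * p2 + d,
        p1 * (1 - p2) - d,
        (1 - p1) * p2 - d,
        (1 - p1) * (1 - p2) + d,
    ])
    if np.any(freqs < -1e-12):
        raise ValueError(
            f"LD r^2={r2} infeasible for MAFs ({p1}, {p2}): a haplotype "
            f"frequency would be negative")
    return np.clip(freqs, 0.0, 1.0)


def generate_genotypes(mafs, ld_pairs, n: int, seed=None,
                       names: list[str] | None = None) -> np.ndarray:
    """Genotype matrix (n x n_snps) of minor-allele counts 0/1/2.

    Marginal genotype frequencies follow Hardy-Weinberg proportions in
    expectation.  ``ld_pairs`` entries are (i, j, r^2) — indices or names —
    generated jointly at the haplotype level; a SNP may appear in at most
    one pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(mafs, float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
    p = len(mafs)
    name_idx = {nm: i for i, nm in enumerate(names)} if names else {}
    pairs = []
    seen: set[int] = set()
    for a, b, r2 in ld_pairs:
        i = name_idx[a] if isinstance(a, str) else int(a)
        j = name_idx[b] if isinstance(b, str) else int(b)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r^2 must be in [0, 1], got {r2}")
        if i in seen or j in seen:
            raise ValueError("a SNP may appear in at most one LD pair")
        seen.update((i, j))
        pairs.append((i, j, float(r2)))

    g = np.empty((n, p), dtype=np.int8)
    for i, j, r2 in pairs:
        freqs = _haplotype_freqs(mafs[i], mafs[j], r2)
        # two haplotypes per subject; haplotype 0=AB, 1=Ab, 2=aB, 3=ab
        hap = rng.choice(4, size=(n, 2), p=freqs)
        g[:, i] = np.sum(hap <= 1, axis=1)          # carries minor allele at i
        g[:, j] = np.sum((hap == 0) | (hap == 2), axis=1)
    for k in range(p):
        if k not in seen:
            g[:, k] = rng.binomial(2, mafs[k], size=n)
    return g


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

def generate_metabolites(latent_corr, genotype_effects, genotypes, n: int,
                         seed=None, metabolite_names: list[str] | None = None,
                         snp_names: list[str] | None = None,
                         covariate_shifts: list[tuple[np.ndarray, str, float]] | None = None,
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Continuous metabolite matrix from a Gaussian copula.

    Latent standard-normal variables with correlation ``latent_corr`` are
    shifted by the genotype (and optional covariate) effects — per-allele
    shifts in latent-SD units — and pushed through log-normal marginals, so
    pairwise Spearman correlations hit ``(6/pi)·asin(rho/2)`` and every
    effect is a location shift on the log scale.

    Returns the assay-scale DataFrame and the latent (log-scale, unit-SD
    noise) matrix used by the outcome model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = np.asarray(latent_corr, float)
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise ValueError(f"latent correlation matrix is not positive "
                         f"semidefinite (smallest eigenvalue {w.min():.3e})")
    names = metabolite_names or list(METABOLITES)[: C.shape[0]]
    root = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n, C.shape[0])) @ root.T

    m_idx = {m: k for k, m in enumerate(names)}
    if genotype_effects:
        s_idx = {s: k for k, s in enumerate(snp_names)} if snp_names else {}
        for snp, met, beta in genotype_effects:
            sj = s_idx[snp] if isinstance(snp, str) else int(snp)
            mj = m_idx[met] if isinstance(met, str) else int(met)
            gcol = np.asarray(genotypes)[:, sj].astype(float)
            z[:, mj] += beta * (gcol - gcol.mean())
    for col, met, shift in covariate_shifts or []:
        mj = m_idx[met] if isinstance(met, str) else int(met)
        z[:, mj] += shift * (np.asarray(col, float) - np.asarray(col, float).mean())

    out = {}
    for k, m in enumerate(names):
        mu, sig = LOGNORMAL_MARGINALS.get(m, (0.0, 1.0))
        out[m] = np.exp(mu + sig * z[:, k])
    return pd.DataFrame(out), z


# ---------------------------------------------------------------------------
# Outcome and matched sampling
# ---------------------------------------------------------------------------

def _environment(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Background variables with the study's design structure: two source
    cohorts (the larger mixed-sex one and a smaller all-female one whose
    samples were mostly non-fasting), age, sampling-year group, smoking."""
    cohort = np.where(rng.random(n) < 0.78, "VIP", "MSP")
    sex = np.where(cohort == "MSP", "female",
                   np.where(rng.random(n) < 0.47, "female", "male"))
    u = rng.random(n)
    fasting = np.empty(n, dtype=object)
    vip = cohort == "VIP"
    fasting[vip] = np.select(
        [u[vip] < 0.02, u[vip] < 0.21], ["<4h", "4-8h"], "≥8h")
    fasting[~vip] = np.select(
        [u[~vip] < 0.96, u[~vip] < 0.99], ["<4h", "4-8h"], "≥8h")
    age = rng.normal(60.0, 8.0, size=n).clip(30, 85)
    year_group = rng.choice(["Y1", "Y2", "Y3", "Y4"], size=n)
    smoking = rng.choice(["current", "ex", "never"], size=n, p=[0.20, 0.17, 0.63])
    return pd.DataFrame({"cohort": cohort, "sex": sex, "fasting": fasting,
                         "age": age, "year_group": year_group,
                         "smoking": smoking})


@dataclass
class SyntheticCohort:
    """A generated matched case-control dataset plus its ground truth."""
    table: CohortTable
    truth_dag: DAG
    continuous_metabolites: pd.DataFrame
    n_cases: int
    n_controls: int
    shortfall: int = 0  # matched sets emitted with fewer controls than asked


def generate_outcome_and_match(metabolites: pd.DataFrame, latent: np.ndarray,
                               genotypes: np.ndarray, env: pd.DataFrame,
                               spec: TruthSpec, n_cases: int,
                               controls_per_case: int = 2,
                               seed=None) -> SyntheticCohort:
    """Draw the outcome and sample matched case-control sets from the pool.

    The outcome follows a logistic model on the latent metabolite scores
    (per-SD coefficients from ``spec.outcome_log_or`` plus the single
    product term), with the intercept calibrated so the pool incidence
    equals ``spec.baseline_risk`` per 100,000.  For each sampled case,
    ``controls_per_case`` non-cases are drawn without replacement matching
    exactly on sex, cohort, fasting status and sampling-year group, and on
    age within ``spec.age_caliper`` years; when a set cannot be filled the
    caliper is doubled (logged) before a shortfall is recorded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if controls_per_case < 1:
        raise ValueError("controls_per_case must be >= 1")
    n = len(metabolites)
    m_idx = {m: k for k, m in enumerate(metabolites.columns)}

    lp = np.zeros(n)
    for v, beta in spec.outcome_log_or.items():
        lp += beta * latent[:, m_idx[v]]
    if spec.interaction is not None:
        a, b, beta = spec.interaction
        lp += beta * latent[:, m_idx[a]] * latent[:, m_idx[b]]
    target = spec.baseline_risk / 1e5

    def mean_risk(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lp))))) - target

    alpha = brentq(mean_risk, -30.0, 5.0)
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + lp)))

    case_pool = np.flatnonzero(y)
    rng.shuffle(case_pool)
    if len(case_pool) < n_cases:
        log.warning("pool yielded %d cases, fewer than the %d requested",
                    len(case_pool), n_cases)
    cases = np.sort(case_pool[:n_cases])

    # group non-cases by exact matching stratum, sorted by age for caliper search
    strata: dict[tuple, list[int]] = {}
    noncase = np.flatnonzero(~y)
    keys = list(zip(env["sex"], env["cohort"], env["fasting"], env["year_group"]))
    for i in noncase:
        strata.setdefault(keys[i], []).append(i)
    ages = env["age"].to_numpy()
    for k in strata:
        strata[k].sort(key=lambda i: ages[i])
    used: set[int] = set()

    rows_case, rows_ctrl, set_ids = [], [], []
    shortfall = 0
    for s, ci in enumerate(cases):
        pool = strata.get(keys[ci], [])
        caliper = spec.age_caliper
        picked: list[int] = []
        while len(picked) < controls_per_case and caliper <= 64 * spec.age_caliper:
            eligible = [i for i in pool
                        if i not in used and abs(ages[i] - ages[ci]) <= caliper]
            extra = [i for i in eligible if i not in picked]
            take = min(controls_per_case - len(picked), len(extra))
            if take:
                sel = rng.choice(len(extra), size=take, replace=False)
                picked.extend(extra[j] for j in sorted(sel))
            if len(picked) < controls_per_case:
                caliper *= 2
                log.info("matching: widening age caliper to %.1f y for case %d",
                         caliper, s)
        if len(picked) < controls_per_case:
            shortfall += controls_per_case - len(picked)
            log.warning("matching exhausted for case %d: %d/%d controls",
                        s, len(picked), controls_per_case)
        used.update(picked)
        rows_case.append(ci)
        rows_ctrl.append(picked)
        set_ids.append(f"S{s + 1:05d}")

    idx, sets, status = [], [], []
    for ci, ctrls, sid in zip(rows_case, rows_ctrl, set_ids):
        idx.append(ci); sets.append(sid); status.append("1")
        for j in ctrls:
            idx.append(j); sets.append(sid); status.append("0")
    idx = np.asarray(idx)

    df = pd.DataFrame({
        "subject_id": [f"P{k + 1:06d}" for k in range(len(idx))],
        "matched_set_id": sets,
        "crc": pd.Categorical(status, categories=["0", "1"], ordered=True),
    })
    for col in ("sex", "cohort", "fasting", "year_group", "smoking"):
        df[col] = pd.Categorical(env[col].to_numpy()[idx])
    df["age"] = ages[idx]
    for k, snp in enumerate(spec.snp_names):
        df[snp] = pd.Categorical(
            genotypes[idx, k].astype(str), categories=["0", "1", "2"],
            ordered=True)
    # continuous concentrations travel with the table as "<name>_conc"
    met = metabolites.iloc[idx].reset_index(drop=True)
    for m in met.columns:
        df[m + "_conc"] = met[m].to_numpy()

    roles = {"crc": "outcome", "smoking": "environment"}
    roles.update({s: "snp" for s in spec.snp_names})
    roles.update({v: "matching" for v in ("sex", "cohort", "fasting", "year_group")})
    table = CohortTable(df, roles)
    return SyntheticCohort(
        table=table, truth_dag=spec.truth_dag(),
        continuous_metabolites=met, n_cases=int(len(cases)),
        n_controls=int(sum(len(c) for c in rows_ctrl)), shortfall=shortfall)


def generate_cohort(spec: TruthSpec, n_cases: int = 613,
                    controls_per_case: int = 2,
                    pool_size: int | None = None) -> SyntheticCohort:
    """End-to-end generation: pool, genotypes, metabolites, outcome, matching.

    ``pool_size`` defaults to ``1.3 * n_cases / baseline_risk`` so the rare
    outcome yields enough cases at the configured cumulative incidence.
    """
    master = np.random.default_rng(spec.seed)
    r_geno, r_met, r_out = master.spawn(3)
    if pool_size is None:
        pool_size = int(1.3 * n_cases / (spec.baseline_risk / 1e5))
    env = _environment(pool_size, master)
    g = generate_genotypes(spec.snp_mafs, spec.ld_pairs, pool_size, r_geno,
                           names=spec.snp_names)
    shifts = []
    for cov, level, met, beta in spec.covariate_effects:
        shifts.append(((env[cov] == level).to_numpy().astype(float), met, beta))
    mets, latent = generate_metabolites(
        spec.latent_corr, spec.genotype_metabolite_effects, g, pool_size,
        r_met, metabolite_names=spec.metabolites, snp_names=spec.snp_names,
        covariate_shifts=shifts)
    return generate_outcome_and_match(mets, latent, g, env, spec, n_cases,
                                      controls_per_case, r_out)


# ---------------------------------------------------------------------------
# Direct matched-set simulation (for estimator calibration)
# ---------------------------------------------------------------------------

def simulate_matched_sets(n_sets: int, controls_per_case: int,
                          betas: np.ndarray, rng,
                          corr: np.ndarray | None = None,
                          interaction: tuple[int, int, float] | None = None,
                          endpoint_probs: np.ndarray | None = None,
                          endpoint_betas: np.ndarray | None = None,
                          ) -> pd.DataFrame:
    """Matched sets drawn exactly from the conditional logistic model.

    Within each set of ``controls_per_case + 1`` subjects with covariates
    ``x ~ N(0, corr)``, the case index is drawn with probability
    ``softmax(x @ beta)`` — the conditional likelihood itself — so a
    conditional-logistic fit is correctly specified with coefficients
    ``betas``.  Optionally an endpoint label is drawn per set with
    endpoint-specific coefficients (for heterogeneity tests).

    Returns a long DataFrame with columns ``set_id, case, x0..x{p-1}``
    (plus ``endpoint``).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    betas = np.atleast_1d(np.asarray(betas, float))
    p = betas.size
    m = controls_per_case + 1
    if corr is None:
        x = rng.standard_normal((n_sets, m, p))
    else:
        root = np.linalg.cholesky(np.asarray(corr, float))
        x = rng.standard_normal((n_sets, m, p)) @ root.T

    if endpoint_probs is not None:
        ep = rng.choice(len(endpoint_probs), size=n_sets, p=endpoint_probs)
        B = np.asarray(endpoint_betas, float)  # (n_endpoints, p)
        eta = np.einsum("smp,sp->sm", x, B[ep])
    else:
        ep = None
        eta = x @ betas
    if interaction is not None:
        i, j, bi = interaction
        eta = eta + bi * x[:, :, i] * x[:, :, j]
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n_sets)
    case_idx = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)

    rows = {
        "set_id": np.repeat(np.arange(n_sets), m),
        "case": (np.tile(np.arange(m), n_sets)
                 == np.repeat(case_idx, m)).astype(int),
    }
    for k in range(p):
        rows[f"x{k}"] = x[:, :, k].reshape(-1)
    df = pd.DataFrame(rows)
    if ep is not None:
        df["endpoint"] = np.repeat(ep, m)
    return df
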