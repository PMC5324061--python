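"""Descriptive statistics, quality checks and discretization.

Everything that turns raw cohort columns into the categorical analysis
table the network learners consume:

* quantile discretization with cut-offs taken from the *control*
  distribution (the case-control convention: categories describe where a
  subject falls relative to the disease-free population);
* collapsing of rare genotypes into a two-group common/variant coding;
* Hardy-Weinberg equilibrium tests (Pearson chi-square, exact test when
  expected counts are small);
* pairwise-complete Spearman correlation matrices with complete-linkage
  hierarchical clustering on the correlation distance ``1 - r``;
* case-control baseline comparisons (Mann-Whitney U for continuous
  variables, chi-square for categorical) with Bonferroni-adjusted
  thresholds.

Conventions pinned here (the quantile interpolation rule and the binning
of boundary values) are arbitrary but fixed: quantiles use the empirical
inverse CDF with linear (type-7) interpolation, and bins are left-closed
``[c_{i-1}, c_i)`` with the last bin closed above, matching interval labels
of the form ``<9.0``, ``9.0-15.3``, ``>=15.3``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cohort import MISSING, CohortTable

log = logging.getLogger(__name__)

__all__ = [
    "discretize_by_control_quantiles",
    "collapse_rare_genotypes",
    "hwe_test",
    "spearman_matrix",
    "baseline_comparison",
    "bonferroni_threshold",
    "discretize_cohort",
    "CorrelationReport",
]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # one decimal place where exact ("9.0", "15.3"), full precision otherwise
    return f"{x:.1f}" if abs(x - round(x, 1)) < 1e-12 else f"{x:g}"


def discretize_by_control_quantiles(values, control_mask, k: int = 4
                                    ) -> tuple[pd.Categorical, np.ndarray]:
    """Bin ``values`` into ``k`` ordered groups cut at control quantiles.

    Cut-offs are the (1/k, ..., (k-1)/k) empirical quantiles (linear,
    type-7 interpolation) of the non-missing *control* values; all subjects
    — cases included — are then binned by those cut-offs into left-closed
    intervals, category 1 lowest.  Returns the ordered categorical column
    (NaN where the input is missing) and the cut-off array.
    """
    values = np.asarray(values, float)
    control_mask = np.asarray(control_mask, bool)
    if k < 2:
        raise ValueError("k must be >= 2")
    ctrl = values[control_mask]
    ctrl = ctrl[~np.isnan(ctrl)]
    if np.unique(ctrl).size < k:
        raise ValueError(f"fewer distinct control values than k={k}")
    cutoffs = np.quantile(ctrl, np.arange(1, k) / k, method="linear")
    if np.unique(cutoffs).size < cutoffs.size:
        log.info("tied quantile boundaries; deterministic left-closed binning")
    labels = []
    for i in range(k):
        if i == 0:
            labels.append(f"<{_fmt(cutoffs[0])}")
        elif i == k - 1:
            labels.append(f"≥{_fmt(cutoffs[-1])}")
        else:
            labels.append(f"{_fmt(cutoffs[i - 1])}–{_fmt(cutoffs[i])}")
    if len(set(labels)) < k:  # tied cutoffs duplicate interval labels
        labels = [f"{lab} #{i + 1}" if labels.count(lab) > 1 else lab
                  for i, lab in enumerate(labels)]
    # value == cutoff goes to the upper bin: [c_{i-1}, c_i); tied cutoffs
    # leave the collapsed middle bins deterministically empty
    codes = np.searchsorted(cutoffs, values, side="right")
    codes = np.where(np.isnan(values), -1, codes)
    cat = pd.Categorical.from_codes(codes.astype(int), categories=labels,
                                    ordered=True)
    return cat, cutoffs


def collapse_rare_genotypes(column: pd.Categorical | pd.Series,
                            min_homozygous: int = 40) -> pd.Categorical:
    """Two-group common/variant recoding when homozygous variants are rare.

    Genotype columns are coded by minor-allele count ('0', '1', '2').  If
    the homozygous-variant ('2') count is below ``min_homozygous``, the
    heterozygous and homozygous-variant groups are merged into a single
    'variant' category; otherwise the column is returned unchanged.
    """
    s = pd.Series(column).astype(str)
    counts = s.value_counts()
    n2 = int(counts.get("2", 0))
    if n2 >= min_homozygous:
        return pd.Categorical(s, categories=["0", "1", "2"], ordered=True)
    if int(counts.get("0", 0)) == 0 and int(counts.get("1", 0)) == 0:
        log.warning("genotype column is constant after collapsing")
        return pd.Categorical(np.where(s.isna(), None, "variant"),
                              categories=["variant"])
    merged = s.map({"0": "common", "1": "variant", "2": "variant"})
    return pd.Categorical(merged, categories=["common", "variant"],
                          ordered=True)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts) -> tuple[float, float]:
    """Test genotype counts (n_common, n_het, n_variant) against HWE.

    Expected counts come from the estimated allele frequency; Pearson's
    chi-square with 1 df is used when all expected counts are at least 5,
    otherwise the Levene-Haldane exact test (probabilities of heterozygote
    counts conditional on the allele counts).  Returns (statistic, p);
    the statistic is NaN for the exact branch.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("zero total genotype count")
    q = (2 * n2 + n1) / (2 * n)  # minor-allele frequency
    p = 1 - q
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n0, n1, n2], float)
    if expected.min() >= 5:
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return chi2, float(stats.chi2.sf(chi2, df=1))
    return math.nan, _hwe_exact(n0, n1, n2)


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p-value conditional on allele counts (sum of configurations
    no more probable than the observed one)."""
    n = n0 + n1 + n2
    n_minor = 2 * n2 + n1
    het_values = [h for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)]
    logs = []
    for h in het_values:
        a2 = (n_minor - h) // 2
        a0 = n - h - a2
        lp = (math.lgamma(n + 1) - math.lgamma(a0 + 1) - math.lgamma(h + 1)
              - math.lgamma(a2 + 1) + h * math.log(2)
              + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1)
              - math.lgamma(2 * n + 1))
        logs.append(lp)
    probs = np.exp(logs - np.logaddexp.reduce(logs))
    obs = het_values.index(n1)
    return float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-test significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Pairwise-complete Spearman matrix plus a complete-linkage tree."""
    variables: list[str]
    spearman: pd.DataFrame
    n_pairs: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix on distance 1 - r

    def to_tsv(self, path) -> None:
        self.spearman.to_csv(str(path), sep="\t")

    def merge_list(self) -> list[tuple[int, int, float]]:
        """(cluster_i, cluster_j, height) merges, heights non-decreasing."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]


def spearman_matrix(continuous_table: pd.DataFrame) -> CorrelationReport:
    """Spearman correlations on pairwise-complete observations, with
    complete-linkage hierarchical clustering on the distance ``1 - r``."""
    df = continuous_table.astype(float)
    r = df.corr(method="spearman", min_periods=3)
    notna = df.notna().astype(int).to_numpy()
    n_pairs = pd.DataFrame(notna.T @ notna, index=df.columns,
                           columns=df.columns)
    if r.isna().any().any():
        log.warning("all-missing variable pair(s); correlation cell flagged NaN")
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="complete")
    return CorrelationReport(variables=list(df.columns), spearman=r,
                             n_pairs=n_pairs, linkage=linkage)


# ---------------------------------------------------------------------------
# Baseline case-control comparisons
# ---------------------------------------------------------------------------

def baseline_comparison(table: CohortTable,
                        continuous: pd.DataFrame | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable case-control distribution tests.

    Continuous columns (from ``continuous``) are compared with the
    two-sided Mann-Whitney U test; categorical table variables with the
    chi-square test (no continuity correction).  Matching variables are
    skipped — they are balanced by design.  The Bonferroni-adjusted
    threshold ``alpha / m`` uses the number of continuous (metabolite)
    tests, following the convention of correcting within the marker panel.
    """
    case = table.case_mask.to_numpy() if hasattr(table.case_mask, "to_numpy") \
        else np.asarray(table.case_mask)
    if case.all() or (~case).all():
        raise ValueError("both cases and controls must be present")
    rows = []
    if continuous is not None:
        m = continuous.shape[1]
        thr = bonferroni_threshold(alpha, m) if m else alpha
        for col in continuous.columns:
            x = continuous[col].to_numpy(float)
            ok = ~np.isnan(x)
            u, p = stats.mannwhitneyu(x[ok & case], x[ok & ~case],
                                      alternative="two-sided")
            rows.append({"variable": col, "test": "mann-whitney",
                         "statistic": float(u), "p": float(p),
                         "adjusted_threshold": thr})
    for v in table.variables("snp", "environment"):
        obs = pd.crosstab(table.data[v], case)
        if obs.shape[1] < 2 or obs.shape[0] < 2:
            continue
        chi2, p, _, _ = stats.chi2_contingency(obs.to_numpy(), correction=False)
        rows.append({"variable": v, "test": "chi-square",
                     "statistic": float(chi2), "p": float(p),
                     "adjusted_threshold": alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-level discretization
# ---------------------------------------------------------------------------

def discretize_cohort(table: CohortTable, k: int = 4,
                      min_homozygous: int = 40,
                      age_k: int = 4) -> tuple[CohortTable, dict[str, np.ndarray]]:
    """Build the categorical analysis table from a generated/loaded cohort.

    Metabolite concentrations (``*_conc`` columns) are discretized into
    ``k`` control-based quantile groups; a continuous ``age`` column, when
    present, becomes an ``age_group`` matching variable (control quartiles);
    genotype columns with rare homozygous variants are collapsed.  Subjects
    missing any metabolite or SNP value are dropped (complete case), and
    matched sets losing their case are dropped entirely.

    Returns the new table and the per-variable cut-off arrays.
    """
    df = table.data.copy()
    roles = dict(table.roles)
    case = np.asarray(table.case_mask)
    cutoffs: dict[str, np.ndarray] = {}

    for col in [c for c in df.columns if c.endswith("_conc")]:
        name = col[:-5]
        cat, cuts = discretize_by_control_quantiles(df[col].to_numpy(float),
                                                    ~case, k)
        df[name] = cat
        roles[name] = "metabolite"
        cutoffs[name] = cuts

    if "age" in df.columns and "age_group" not in roles:
        cat, cuts = discretize_by_control_quantiles(df["age"].to_numpy(float),
                                                    ~case, age_k)
        df["age_group"] = cat
        roles["age_group"] = "matching"
        cutoffs["age_group"] = cuts

    for v in [v for v, r in roles.items() if r == "snp"]:
        df[v] = collapse_rare_genotypes(df[v], min_homozygous=min_homozygous)

    # environmental variables keep their subjects: explicit missing category
    for v in [v for v, r in roles.items() if r == "environment"]:
        if df[v].isna().any():
            col = df[v].astype("category")
            if MISSING not in col.cat.categories:
                col = col.cat.add_categories([MISSING])
            df[v] = col.fillna(MISSING)

    out = CohortTable(df, roles)
    need = out.variables("metabolite", "snp", "outcome")
    complete = ~out.data[need].isna().any(axis=1)
    if not complete.all():
        log.info("dropping %d subjects with incomplete metabolite/SNP data",
                 int((~complete).sum()))
        out = out.subset(complete.to_numpy())
    return out, cutoffs
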