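"""Matched-set regression and absolute-risk estimation.

Conditional logistic regression (CLR) is the workhorse for matched
case-control data: the likelihood conditions on each matched set's case
total, absorbing the matching variables by risk-set stratification so they
never appear as covariates.  On top of a CLR fit this module provides

* crude cross-product odds ratios from 2x2 cell counts,
* linear-trend tests modelling log-transformed concentrations,
* two-way interaction tests (likelihood-ratio on the product term, SNPs
  coded additively 0/1/2),
* heterogeneity likelihood-ratio tests comparing endpoint-specific to
  common association models, and
* marginal risk differences (RDs): absolute standardized risks per
  exposure category obtained from a weighted maximum-likelihood logistic
  fit in which controls are reweighted — within standardization strata —
  so the case-control sample represents a source cohort with a given
  cumulative incidence; confidence intervals by matched-set bootstrap.

Model maximization is delegated to statsmodels (ConditionalLogit for the
matched likelihood, GLM for the weighted fits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from .cohort import CohortTable

log = logging.getLogger(__name__)

__all__ = [
    "CLRFit", "SeparationError", "clr_fit", "crude_or", "trend_test",
    "interaction_test", "heterogeneity_test", "marginal_rd", "RDEstimate",
]


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximizer."""


@dataclass
class CLRFit:
    """A converged conditional-logistic fit."""
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_sets: int
    converged: bool
    score_norm: float
    iterations: int = 0
    excluded: list[str] = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def odds_ratios(self) -> pd.DataFrame:
        se = self.se
        z = stats.norm.ppf(0.975)
        return pd.DataFrame({
            "estimate": self.params,
            "se": se,
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - z * se),
            "ci_high": np.exp(self.params + z * se),
            "p": 2 * stats.norm.sf(np.abs(self.params / se)),
        })

    def summary_tsv(self, path) -> None:
        self.odds_ratios().rename_axis("term").to_csv(str(path), sep="\t")


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _as_frame(data) -> tuple[pd.DataFrame, str, str]:
    """Normalize input to (df, set_col, case_col)."""
    if isinstance(data, CohortTable):
        df = data.data.copy()
        df["_case"] = np.asarray(data.case_mask, int)
        return df, "matched_set_id", "_case"
    df = data
    set_col = "matched_set_id" if "matched_set_id" in df.columns else "set_id"
    case_col = "_case" if "_case" in df.columns else "case"
    return df, set_col, case_col


def _numeric(df: pd.DataFrame, name: str) -> pd.Series:
    col = df[name]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        return pd.to_numeric(col.astype(str), errors="raise")
    return col.astype(float)


def term_columns(df: pd.DataFrame, term: str) -> pd.DataFrame:
    """Expand one model term into numeric design columns.

    Supported forms: ``name`` (numeric as-is; categorical becomes
    reference-coded dummies), ``log(name)`` (natural log, errors on
    non-positive values), ``additive(name)`` (genotype categories 0/1/2 as
    a numeric allele count), and ``a*b`` (elementwise product of two
    single-column terms).
    """
    term = term.strip()
    if "*" in term:
        left, right = (t.strip() for t in term.split("*", 1))
        a, b = term_columns(df, left), term_columns(df, right)
        if a.shape[1] != 1 or b.shape[1] != 1:
            raise ValueError(f"product term {term!r} requires single columns")
        return pd.DataFrame({term: a.iloc[:, 0].to_numpy()
                             * b.iloc[:, 0].to_numpy()}, index=df.index)
    if term.startswith("log(") and term.endswith(")"):
        name = term[4:-1]
        x = df[name].astype(float)
        if (x <= 0).any():
            raise ValueError(f"log({name}): non-positive values present")
        return pd.DataFrame({term: np.log(x)}, index=df.index)
    if term.startswith("additive(") and term.endswith(")"):
        name = term[9:-1]
        return pd.DataFrame({term: _numeric(df, name)}, index=df.index)
    col = df[term]
    if isinstance(col.dtype, pd.CategoricalDtype):
        cats = list(col.cat.categories)
        out = {}
        for c in cats[1:]:
            out[f"{term}[{c}]"] = (col == c).astype(float).to_numpy()
        return pd.DataFrame(out, index=df.index)
    if col.dtype == object:
        return term_columns(df.assign(**{term: col.astype("category")}), term)
    return pd.DataFrame({term: col.astype(float)}, index=df.index)


def design_matrix(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.concat([term_columns(df, t) for t in terms], axis=1)
    if X.columns.duplicated().any():
        raise ValueError(f"collinear/duplicate terms in {terms}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design matrix for {terms} is rank deficient")
    return X


# ---------------------------------------------------------------------------
# Conditional logistic regression
# ---------------------------------------------------------------------------

def _clr_newton(X: np.ndarray, case_row: np.ndarray, starts: np.ndarray,
                max_abs_beta: float, tol: float = 1e-10, maxiter: int = 60
                ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton-Raphson with step-halving for the 1-case-per-set likelihood.

    Rows are ordered by matched set (``starts`` indexes set boundaries);
    ``case_row`` flags each set's case.  The conditional log-likelihood is
    ``sum_s [x_case.b - log sum_i exp(x_i.b)]``; gradient and Hessian have
    the usual softmax forms, evaluated with ``np.add.reduceat`` so the fit
    is a handful of vectorized passes regardless of the number of sets.
    """
    n, k = X.shape
    beta = np.zeros(k)
    set_of_row = np.repeat(np.arange(starts.size),
                           np.diff(np.append(starts, n)))
    x_case = X[case_row]

    def eval_at(b):
        eta = X @ b
        m = np.maximum.reduceat(eta, starts)
        ee = np.exp(eta - m[set_of_row])
        denom = np.add.reduceat(ee, starts)
        ll = float(np.sum(eta[case_row] - m - np.log(denom)))
        p = ee / denom[set_of_row]
        mu = np.add.reduceat(p[:, None] * X, starts, axis=0)   # (S, k)
        grad = x_case.sum(axis=0) - mu.sum(axis=0)
        H = -(X.T @ (p[:, None] * X) - mu.T @ mu)
        return ll, grad, H

    ll, grad, H = eval_at(beta)
    it = 0
    for it in range(1, maxiter + 1):
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(H) @ grad
        new = beta + step
        ll_new, grad_new, H_new = eval_at(new)
        halvings = 0
        while not np.isfinite(ll_new) or ll_new < ll - 1e-12:
            step *= 0.5
            halvings += 1
            if halvings > 30:
                break
            new = beta + step
            ll_new, grad_new, H_new = eval_at(new)
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, ll, grad, H = new, ll_new, grad_new, H_new
        if np.max(np.abs(beta)) > max_abs_beta:
            # the conditional likelihood keeps improving as |beta| diverges:
            # complete separation within matched sets
            raise SeparationError(
                f"apparent complete separation: |beta| exceeds "
                f"{max_abs_beta} before the score vanishes")
        if rel < tol and np.max(np.abs(grad)) < 1e-6:
            break
    cov = np.linalg.pinv(-H)
    return beta, cov, ll, grad, it


def clr_fit(data, terms: list[str], max_abs_beta: float = 15.0) -> CLRFit:
    """Fit a conditional logistic regression by maximum likelihood.

    ``data`` is a :class:`~bnepi.cohort.CohortTable` or a long DataFrame
    with set/case columns; ``terms`` are model terms (see
    :func:`term_columns`).  Matching is absorbed by stratification on the
    matched-set identifier; sets without a case or without a control carry
    no information and are dropped.  Covariates constant within every
    matched set are inestimable and silently excluded (the conditional
    likelihood does not involve them); complete separation is detected and
    raised as :class:`SeparationError` rather than returned as a runaway
    estimate.

    Maximization is Newton-Raphson with step-halving, converging when the
    relative log-likelihood change falls below 1e-10 (score component
    magnitudes below 1e-6 at the optimum).  Sets with several cases fall
    back to the general conditional likelihood of statsmodels.
    """
    df, set_col, case_col = _as_frame(data)
    y = df[case_col].astype(int).to_numpy()
    groups = df[set_col].to_numpy()
    X = design_matrix(df, terms)

    # exclude covariates with no within-set variation
    excluded = []
    keep = []
    for c in X.columns:
        v = pd.Series(X[c].to_numpy()).groupby(pd.Series(groups)).nunique()
        if (v <= 1).all():
            excluded.append(c)
            log.info("term %r constant within every matched set; excluded", c)
        else:
            keep.append(c)
    if not keep:
        raise SeparationError(
            "no discordant matched sets: every covariate is constant within "
            "every set; the conditional likelihood is flat")
    X = X[keep]

    # order rows by set; drop uninformative sets
    order = np.argsort(groups, kind="stable")
    Xo = X.to_numpy()[order]
    yo = y[order]
    go = groups[order]
    boundaries = np.flatnonzero(np.r_[True, go[1:] != go[:-1]])
    sizes = np.diff(np.append(boundaries, go.size))
    cases_per_set = np.add.reduceat(yo, boundaries)
    ok_sets = (cases_per_set >= 1) & (cases_per_set < sizes)
    if not ok_sets.all():
        keep_rows = np.repeat(ok_sets, sizes)
        Xo, yo, go = Xo[keep_rows], yo[keep_rows], go[keep_rows]
        boundaries = np.flatnonzero(np.r_[True, go[1:] != go[:-1]])
        cases_per_set = np.add.reduceat(yo, boundaries)
    n_sets = boundaries.size

    if np.all(cases_per_set == 1):
        beta, cov, llf, grad, it = _clr_newton(Xo, yo.astype(bool),
                                               boundaries, max_abs_beta)
        score_norm = float(np.max(np.abs(grad)))
        converged = score_norm < 1e-4
    else:  # several cases per set: general conditional likelihood
        model = ConditionalLogit(yo, Xo, groups=go)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
            try:
                res = model.fit(method="newton", start_params=res.params,
                                maxiter=100, disp=False)
            except Exception:
                pass
        beta = np.asarray(res.params, float)
        score = np.asarray(model.score(beta), float)
        if np.max(np.abs(beta)) > max_abs_beta and np.max(np.abs(score)) > 1e-3:
            raise SeparationError(
                f"apparent complete separation: |beta| exceeds "
                f"{max_abs_beta} with non-vanishing gradient")
        cov = np.asarray(res.cov_params(), float)
        llf = float(res.llf)
        score_norm = float(np.max(np.abs(score)))
        converged = score_norm < 1e-4
        it = 0
    return CLRFit(
        params=pd.Series(beta, index=keep),
        cov=pd.DataFrame(cov, index=keep, columns=keep),
        llf=llf, n_sets=int(n_sets), converged=converged,
        score_norm=score_norm, iterations=int(it), excluded=excluded)


def crude_or(cases_exposed: int, controls_exposed: int,
             cases_ref: int, controls_ref: int,
             haldane: bool = False) -> float:
    """Cross-product odds ratio ``(a·d)/(b·c)`` for one exposure cell
    against the reference cell.  Zero cells raise unless ``haldane`` adds
    0.5 to every count."""
    a, b, c, d = cases_exposed, controls_exposed, cases_ref, controls_ref
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell; pass haldane=True for the 0.5 "
                             "correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def trend_test(data, metabolite: str) -> tuple[float, CLRFit]:
    """Linear-trend p-value from CLR on the log-transformed concentration.

    ``metabolite`` names a positive continuous column (for cohort tables,
    the ``<name>_conc`` column is used automatically).  Returns the Wald
    two-sided p-value of the single coefficient and the fit.
    """
    df, _, _ = _as_frame(data)
    col = metabolite + "_conc" if metabolite + "_conc" in df.columns else metabolite
    fit = clr_fit(data, [f"log({col})"])
    beta = float(fit.params.iloc[0])
    se = float(fit.se.iloc[0])
    return float(2 * stats.norm.sf(abs(beta / se))), fit


def interaction_test(data, var1: str, var2: str) -> tuple[float, float]:
    """Likelihood-ratio test of a two-way interaction in CLR.

    Metabolites enter as log-transformed concentrations, SNPs as additive
    0/1/2 allele counts.  Returns (p, product-term coefficient); the LRT
    compares the model with main effects plus the product term to the
    main-effects model (1 df).
    """
    if var1 == var2:
        raise ValueError("interaction of a variable with itself is collinear")
    df, _, _ = _as_frame(data)

    def encode(v: str) -> str:
        if v + "_conc" in df.columns:
            return f"log({v}_conc)"
        if v in df.columns and str(df[v].dtype) in ("category", "object") \
                and set(map(str, pd.unique(df[v].dropna()))) <= {"0", "1", "2"}:
            return f"additive({v})"
        return f"log({v})" if (pd.api.types.is_numeric_dtype(df[v])
                               and (df[v] > 0).all()) else v
    t1, t2 = encode(var1), encode(var2)
    base = clr_fit(data, [t1, t2])
    full = clr_fit(data, [t1, t2, f"{t1}*{t2}"])
    lrt = 2.0 * (full.llf - base.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return p, float(full.params.loc[f"{t1}*{t2}"])


def heterogeneity_test(data, terms: list[str], endpoint_col: str
                       ) -> tuple[float, int, float]:
    """Likelihood-ratio test of effect heterogeneity across case endpoints.

    Each matched set carries its case's endpoint label.  The unrestricted
    model lets the association vary by endpoint (equivalent to fitting the
    duplicated-data model with endpoint-specific coefficients: separate
    conditional likelihood contributions per endpoint); the restricted
    model holds one common coefficient vector.  Returns
    (p, df, statistic); ``df = (n_endpoints - 1) * n_coefficients``.
    """
    df, set_col, case_col = _as_frame(data)
    case_rows = df[df[case_col].astype(int) == 1]
    set_endpoint = case_rows.set_index(set_col)[endpoint_col]
    labels = [e for e in pd.unique(set_endpoint.dropna())]
    if len(labels) < 2:
        raise ValueError("heterogeneity requires at least two case endpoints")

    pooled = clr_fit(data, terms)
    llf_full = 0.0
    p_coef = None
    used = 0
    for e in labels:
        sets_e = set_endpoint.index[set_endpoint == e]
        sub = df[df[set_col].isin(sets_e)]
        if (sub[case_col].astype(int) == 1).sum() == 0:
            log.warning("endpoint %r has no cases; dropped", e)
            continue
        fit_e = clr_fit(sub, terms)
        if p_coef is None:
            p_coef = fit_e.params.size
        llf_full += fit_e.llf
        used += 1
    lrt = 2.0 * (llf_full - pooled.llf)
    dof = (used - 1) * int(p_coef)
    return float(stats.chi2.sf(max(lrt, 0.0), dof)), dof, float(lrt)


# ---------------------------------------------------------------------------
# Marginal risk differences
# ---------------------------------------------------------------------------

@dataclass
class RDEstimate:
    """Standardized absolute-risk differences, cases per 100,000."""
    reference: str
    rd: pd.Series                 # per exposure category (reference = 0)
    ci_low: pd.Series
    ci_high: pd.Series
    risks: pd.Series              # absolute standardized risks per category
    strata: list[str]
    boot_B: int


def _cohort_weights(case: np.ndarray, strata_key: pd.Series,
                    incidence: float) -> np.ndarray:
    """Per-subject weights making the sample represent the source cohort.

    Within each standardization stratum all cohort cases are assumed
    sampled (weight 1) while controls stand in for the disease-free
    remainder: with ``n_case`` stratum cases and cumulative incidence
    ``pi``, the stratum cohort size is ``n_case / pi`` and each control
    receives ``n_case (1 - pi) / (pi · n_ctrl)``.  Strata with cases but no
    controls collapse into the pooled stratum (logged).
    """
    w = np.ones(case.size)
    key = strata_key.astype(str)
    pooled_ratio = case.sum() * (1 - incidence) / (incidence * max((~case).sum(), 1))
    for s in key.unique():
        m = (key == s).to_numpy()
        n_case = int((m & case).sum())
        n_ctrl = int((m & ~case).sum())
        if n_ctrl == 0:
            log.warning("stratum %r has no controls; pooled weight used", s)
            w[m & ~case] = pooled_ratio
            continue
        if n_case == 0:
            w[m & ~case] = pooled_ratio
            continue
        w[m & ~case] = n_case * (1 - incidence) / (incidence * n_ctrl)
    return w


def marginal_rd(data, exposure: str, cumulative_incidence: float,
                strata: list[str] | None = None, boot_B: int = 200,
                seed=None) -> RDEstimate:
    """Marginal risk differences by weighted maximum likelihood.

    ``cumulative_incidence`` is the source-cohort cumulative incidence on
    the probability scale (e.g. 830 per 100,000 -> 0.0083).  Controls are
    reweighted within the standardization strata, a weighted logistic model
    of the outcome on the exposure categories (plus stratum indicators) is
    fitted, and per-category risks are obtained by standardization: the
    weighted average predicted risk with every subject's exposure set to
    the category.  RDs are against the lowest category, scaled per
    100,000, with percentile bootstrap confidence intervals over
    matched-set resampling.
    """
    if not 0 < cumulative_incidence < 1:
        raise ValueError("cumulative_incidence must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df, set_col, case_col = _as_frame(data)
    strata = list(strata or [])
    exposure_col = df[exposure].astype("category")
    levels = [str(c) for c in exposure_col.cat.categories]

    def fit_once(frame: pd.DataFrame) -> pd.Series | None:
        case = frame[case_col].astype(int).to_numpy().astype(bool)
        key = (frame[strata].astype(str).agg("|".join, axis=1)
               if strata else pd.Series("all", index=frame.index))
        w = _cohort_weights(case, key, cumulative_incidence)
        terms = [exposure] + strata
        try:
            X = design_matrix(frame, terms)
        except ValueError:
            return None
        Xc = sm.add_constant(X.to_numpy(), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(case.astype(float), Xc,
                             family=sm.families.Binomial(),
                             freq_weights=w).fit()
        except Exception:
            return None
        # standardization: set everyone's exposure to each level in turn
        # (prediction frames bypass the rank check: a constant exposure is
        # exactly the point)
        risks = {}
        for lv in levels:
            g = frame.copy()
            g[exposure] = pd.Categorical([lv] * len(g),
                                         categories=exposure_col.cat.categories)
            Xg_df = pd.concat([term_columns(g, t) for t in terms], axis=1)
            Xg_df = Xg_df.reindex(columns=X.columns, fill_value=0.0)
            Xg = sm.add_constant(Xg_df.to_numpy(), has_constant="add")
            pr = res.predict(Xg)
            risks[lv] = float(np.average(pr, weights=w))
        return pd.Series(risks)

    risks = fit_once(df)
    if risks is None:
        raise RuntimeError("weighted risk model could not be fitted")
    ref = levels[0]
    rd_point = (risks - risks[ref]) * 1e5

    sets = pd.unique(df[set_col])
    rows_of = {s: np.flatnonzero((df[set_col] == s).to_numpy()) for s in sets}
    boots = []
    for _ in range(boot_B):
        pick = rng.choice(sets, size=sets.size, replace=True)
        rows = np.concatenate([rows_of[s] for s in pick])
        frame = df.iloc[rows].reset_index(drop=True)
        frame[set_col] = np.repeat(np.arange(pick.size),
                                   [rows_of[s].size for s in pick])
        r = fit_once(frame)
        if r is not None:
            boots.append((r - r[ref]) * 1e5)
    if boots:
        bdf = pd.DataFrame(boots)
        lo = bdf.quantile(0.025)
        hi = bdf.quantile(0.975)
    else:
        lo = rd_point.copy()
        hi = rd_point.copy()
    # the interval always contains the point estimate
    lo = pd.concat([lo, rd_point], axis=1).min(axis=1)
    hi = pd.concat([hi, rd_point], axis=1).max(axis=1)
    return RDEstimate(reference=ref, rd=rd_point, ci_low=lo, ci_high=hi,
                      risks=risks * 1e5, strata=strata, boot_B=boot_B)
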