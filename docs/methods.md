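# Methods

`bnepi` implements a bootstrap-averaged Bayesian-network analysis of a
matched case-control metabolomics/genetics study, together with the
matched-set regression machinery such a study reports alongside the
networks, and a synthetic cohort generator that makes the whole pipeline
testable end to end. This note records the models, the conventions that
had to be pinned, and what the synthetic benchmark does and does not show.

## The statistical model

All network analyses operate on a fully categorical subject-by-variable
table: metabolite concentrations in control-based quantile groups, SNP
genotypes as minor-allele-count categories (collapsed to common/variant
when homozygous variants are rare), and categorical background variables.
A discrete Bayesian network over these variables factorizes the joint
distribution as `P(x) = prod_v P(x_v | pa(x_v))` with multinomial
conditionals. An edge between two variables means they are dependent
given everything else the graph retains — the "independent association"
reading used when such networks are applied to risk-factor panels.

### Scoring and testing conventions

* **AIC.** Maximized `logLik − k`, one penalty unit per free parameter:
  a node of cardinality `c` with parent-configuration count `q`
  contributes `(c−1)·q` parameters. Parent configurations unobserved in
  the data contribute zero log-likelihood but their parameters still
  count. This keeps the score decomposable and exactly equal across
  Markov-equivalent DAGs (tested to 1e−9).
* **G² conditional-independence test.** `G² = 2·N·MI(x; y | Z)` summed
  over observed strata of `Z`, referred to a chi-square with
  `(|x|−1)(|y|−1)·prod|z|` degrees of freedom. Empty strata add zero to
  the statistic; the degrees of freedom are *not* reduced for them. Both
  choices are dialects of the asymptotic test; they are fixed here so
  bootstrap replicates are comparable.
* **Conditioning-set cap.** The asymptotic test loses its calibration in
  sparse strata (quartile variables at n≈1,650 give ≥64 strata for three
  conditioners), so any requested test with more than `max_cond = 3`
  conditioning variables is skipped and dependence is assumed. The cap is
  a config knob.

### Structure learners

Three learners are run inside every bootstrap replicate:

* **Hill climbing (HC):** greedy add/delete/reverse search from the empty
  graph, single best strictly improving move per step, family-score
  caching, no restarts. Ties broken lexicographically by (move kind,
  source, target) for bit-reproducibility.
* **IAMB:** per-node Markov-blanket discovery (forward phase adds the
  strongest conditionally dependent variable, interleaved backward phase
  removes members rendered independent), AND-rule symmetrization,
  neighbour determination by sepset search within blankets, collider
  orientation, Meek-style propagation, deterministic completion.
* **MMHC:** MMPC skeleton per node with the max-min heuristic (permanent
  exclusion of candidates once separated; incremental subset testing),
  AND-rule symmetrization, then HC restricted to the skeleton.

Greedy hill climbing carries no global-optimality guarantee: data from a
collider whose parameterization masks the marginal parent-child
dependence send the search into the complete-graph local optimum. On
generic random joint distributions the greedy optimum and the exhaustive
3-node optimum coincide (tested over 20 instances against enumeration of
all 25 DAGs); robustness on real-scale problems comes from bootstrap
averaging, not from the single search.

### Bootstrap model averaging

`B` nonparametric resamples of subjects are drawn (the subject, not the
matched set, is the resampling unit: the learning stage treats case
status as one variable among many, and matching is honoured only in the
regression module). One DAG is learned per resample and, for every
variable pair, the *edge confidence* is the frequency with which the pair
is connected in either direction. The inclusion threshold is estimated
from the confidence distribution itself: the empirical CDF of the
confidences is compared with the ideal two-level CDF in which noise pairs
sit at confidence 0 and true edges at 1, and the cut minimizing the L1
distance (searched exhaustively over observed values) is taken. Kept
pairs are oriented by majority directional frequency; ties are broken
lexicographically and flagged; if majority orientations form a cycle the
offending relation is re-oriented to its minority direction, and deleted
only if both directions cycle.

A property worth knowing: bootstrap confidences of *null* pairs are not
near zero. The resampling world treats the observed sample as truth, so
a pair whose in-sample G² happens to land in the upper chi-square tail is
"dependent" in most replicates; isolated null 4-level pairs at n≈1,650
carry confidences around 0.3–0.5. That is exactly why a data-driven
threshold (which lands near 50% on the benchmark, for every algorithm)
is needed rather than a fixed small cutoff.

### Odds ratios from the network

`OR = [P(case|E)/P(control|E)] / [P(case|R)/P(control|R)]` with the
conditional probabilities computed by exact variable elimination — a
deterministic evaluation of the same estimand that stochastic
conditional-probability queries approximate. CPTs used for OR queries are
fitted with add-0.5 smoothing so sparse strata give finite odds (learning
itself uses unsmoothed maximum likelihood). Adjustment for design
variables is by standardization: outcome probabilities are averaged over
the empirical joint distribution of the matching variables among
controls before forming the odds. Published analyses that report
"adjusted for the matching variables" network odds ratios rarely state
the adjustment construction; standardization over the control
distribution is this package's disclosed choice.

### Matched-set regression

Conditional logistic regression maximizes
`prod_s exp(x_case·β) / Σ_{i in s} exp(x_i·β)` by Newton–Raphson with
step-halving (convergence: relative log-likelihood change < 1e−10 and
score components < 1e−6; covariance from the inverse observed
information). Matching variables are absorbed by the stratification and
never entered as covariates; set-constant covariates are inestimable and
excluded; complete separation is raised as an error once `|β|` exceeds 15
while the likelihood still improves. Sets with more than one case fall
back to the general conditional likelihood in statsmodels.

* **Trend tests** model the log-transformed concentration (scale
  invariance within sets is exact).
* **Interaction tests** are 1-df likelihood-ratio tests of the product
  term, metabolites log-transformed, SNPs coded additively 0/1/2.
* **Heterogeneity tests** compare endpoint-specific to common-coefficient
  models: the unrestricted log-likelihood is the sum of per-endpoint
  conditional fits (each matched set contributes to its case's endpoint),
  with `(E−1)·p` degrees of freedom — the direct-fit equivalent of the
  duplicated-data construction.
* **Marginal risk differences** reconstruct a weighted
  maximum-likelihood estimator whose original formulas are in an
  inaccessible companion reference: within standardization strata, all
  cohort cases are assumed sampled (weight 1) and each control stands in
  for `n_case(1−π)/(π·n_ctrl)` cohort non-cases at cumulative incidence
  π; a weighted logistic fit plus g-computation gives per-category
  standardized risks, differenced against the lowest category and scaled
  per 100,000, with percentile bootstrap CIs over matched-set resampling
  (the interval is widened to contain the point estimate if a finite
  bootstrap misses it). This reconstruction is validated only as an
  order-of-magnitude property — under a quartile OR of 0.63 and
  cumulative incidence 830/100,000 it yields a risk reduction of a few
  hundred cases per 100,000 — never bit-exactly.

## The synthetic cohort generator

The generator emulates the statistical structure of a prospective
nested case-control study of one-carbon metabolism and colorectal
cancer; its defaults are the study conditions wherever those are known.

* **Metabolites.** A 14-node linear Gaussian structural model on the
  latent scale encodes the published correlation clusters (choline
  pathway chain, B-vitamin cluster, serine→glycine, methionine/
  transsulfuration chain, folate and B12 into homocysteine). Path
  coefficients are placed so the implied Pearson correlations of the
  directly related pairs equal `2·sin(π·r_S/6)` of the published Spearman
  values (glycine–serine 0.52, choline–betaine 0.40,
  folate–homocysteine −0.37, B12–homocysteine −0.28, choline–methionine
  0.28); a Gaussian copula with log-normal marginals (medians and IQRs
  placed at adult plasma values) then makes the realized Spearman
  correlations hit those targets exactly in expectation. Every effect on
  a metabolite is a location shift on the log scale, in units of the
  within-group latent SD.
* **Genotypes.** 17 SNPs at plausible European minor-allele frequencies,
  three of them deliberately rare so the genotype-collapsing rule is
  exercised; Hardy-Weinberg proportions hold marginally, and within-gene
  LD pairs are generated at the haplotype level with feasibility checks
  on the requested r². The MTHFR 677 variant shifts homocysteine by
  +0.5 SD per allele.
* **Background variables.** Two source cohorts (78% a mixed-sex cohort,
  22% an all-female screening cohort whose samples are 96% short-fasted),
  age ~ N(60, 8²), uniform sampling-year groups, smoking (current smokers
  shift vitamin B6 by −0.5 SD). The cohort→sex and cohort→fasting design
  dependencies are part of the ground-truth graph.
* **Outcome and matching.** The outcome is logistic on the latent
  metabolite scores with intercept calibrated so the pool incidence is
  830 per 100,000. Default effects are folate +0.7, vitamin B6 −0.7,
  vitamin B2 −0.7 per SD with a +0.25 B2×B6 product term. These are
  *validation-regime* effects: large enough that the injected outcome
  edges are recoverable above the bootstrap threshold at the study's
  sample size, which is what the recovery benchmark must demonstrate.
  The study's own effect sizes (quartile OR ≈ 0.63 ⇒ ≈0.18 per SD) sit
  below the inclusion threshold at this sample size and
  are used here only for the risk-difference checks
  (`TruthSpec(outcome_log_or=...)`). Controls are sampled without
  replacement, 2 per case, matched exactly on sex, cohort, fasting and
  sampling-year group and on age within a ±2-year caliper (matched designs rarely state their calipers; it is a parameter). The caliper
  doubles, with logging, when a set cannot be filled.

What the generator does **not** emulate: assay noise and batch effects,
storage degradation, dietary questionnaires, genuine survival time (the
incidence-density analog is a single event-time draw), or missingness
(tables are complete by default). Passing tests therefore show the
machinery is correct and calibrated under a faithful, Markovian,
log-normal world — they do not certify recovery rates on real cohort
data, where effects are weaker and unfaithfulness is possible.

## Numerical and testing choices

* All randomness flows from one integer seed through
  `numpy.random.Generator.spawn` child streams per stage.
* Quantile cut-offs use the empirical inverse CDF with linear (type-7)
  interpolation on controls; bins are left-closed `[c_{i−1}, c_i)` with
  the last bin closed above; boundary values go up.
* Hardy-Weinberg testing switches from the 1-df Pearson chi-square to the
  Levene–Haldane exact test when any expected genotype count is below 5.
* The exact-inference elimination order is greedy minimum-resulting-
  factor-size with lexicographic tie-break.
* Benchmark problem sizes used by the test suite: 550 cases / 1,100
  controls (≈38 analysis variables), B = 100 bootstrap replicates for HC
  and IAMB and 40–50 for MMHC, five repeated cohorts for the
  edge-separation check, 500-replicate calibration suites for the
  regression tests, and 1,000-draw null suites for the G², trend and
  interaction calibrations. These sizes keep the full suite within a
  routine single-CPU run while leaving the stated tolerances intact.

## Known limitations

* IAMB at these sample sizes misses the weaker injected outcome edges
  (its AND-rule symmetrization and backward tests cost sensitivity); the
  score-based learner is the sensitive one, the same ordering reported
  when these algorithms are compared on epidemiological data. The
  edge-separation benchmark is therefore defined on the HC networks.
* Bootstrap confidences of null pairs concentrate well above zero (see
  above); interpreting raw confidences without the estimated threshold
  overstates support.
* The risk-difference estimator is a reconstruction; only its sign,
  scale, and rare-disease behaviour are validated.
* Exact inference assumes the learned DAG is sparse enough for variable
  elimination; the averaged networks here are far below any problematic
  treewidth.
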