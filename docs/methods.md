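# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Score construction

The continuous mortality risk score is a fixed linear functional of ten
methylation beta values, `cont.MRscore = Σₖ wₖ βₖ`, with published
weights stored in `scores.MRSCORE_WEIGHTS`. Nine weights are negative
(hypomethylation is the risk direction); cg08362785 is the single
positive-weight, hypermethylated marker. Subjects missing any of the ten
betas receive a missing score and are flagged rather than dropped
silently.

The count score marks a CpG *aberrant* when its beta lies in the extreme
quartile in the risk direction. Two conventions are deliberately fixed
and documented because the original cutoff values are not public:

* **Quantile convention.** Cutoffs are the first (hypo) or third (hyper)
  sample quartile with linear interpolation between order statistics
  (the numpy default). Fixed cutoffs can instead be supplied as a
  threshold table.
* **Boundary convention.** Aberrance is inclusive (`β ≤ cutoff` for
  hypo, `β ≥ cutoff` for hyper), which keeps the all-tied degenerate
  column well defined (every subject aberrant, with a warning).

Reporting categories are 0, 1, 2–5, and >5 aberrant CpGs.

Age acceleration is the OLS residual of DNAm age on chronological age,
computed *within each analysis sample* (per-subset residuals match
per-subset correlation structure); it is exactly uncorrelated with age
and invariant to location shifts of DNAm age by construction.

Probe QC removes sex-chromosome probes, masks values whose detection
p-value exceeds 0.01, and removes probes whose missing fraction
(after masking) exceeds 10%; the exclusion report attributes each removal
to the first failing rule (sex chromosome, raw missingness, detection).

Z-standardization for per-SD effects always uses the analysis sample's
own mean and SD (ddof=1), because sampling designs that oversample deaths
shift the indicator distributions between subsets.

## Frailty index

FI = deficits present / deficits considered. Screening retains deficits
with overall prevalence > 1%, prevalence ≤ 50% among subjects aged 50–60
(the "early saturation" rule — treated as one rule with one quantitative
anchor), and a positive age trend, operationalized as a positive Spearman
correlation with age at p < 0.05 (the criterion names accumulation with
age but not a test; a rank test is robust to the Bernoulli coding).
Relevance to general health cannot be judged from the panel alone and is
exposed as a user-supplied keep-list.

Missing deficit values are imputed by chained logistic regressions: each
incomplete deficit is modelled on age, sex, and all other deficits at
their current filled values, with Bernoulli draws from fitted
probabilities; three sweeps follow a marginal-prevalence initialization.
The library default is m = 20 imputations (matching the conventional
choice for stable pooled inference); the pipeline default is m = 5, which
is sufficient for the smooth, low-missingness panels it generates. A
small ridge penalty (scikit-learn's default) stabilizes the per-deficit
fits; with ~3% missingness per deficit the induced bias is negligible
against the Monte-Carlo error of the draws.

Downstream, FI-outcome regressions are fitted once per completed panel
and pooled by Rubin's rules; survival and accuracy analyses use the mean
FI across imputations (a single value per subject is required for risk
prediction).

## Association models

FI (in % units) is regressed on the z-scored indicator(s) with a random
intercept for methylation experiment batch, estimated by REML
(statsmodels MixedLM); with a single batch the model degrades to OLS with
a warning. The model ladder is configuration, not code: Model 1 adjusts
for age, sex, and leukocyte-composition covariates; Model 2 adds smoking
and alcohol; Model 3 enters the mortality score and age acceleration
jointly. Leukocyte proportions sum to one, so one category (lymphocytes)
is omitted from the default covariate list to keep the design full rank.

Subset estimates are pooled by DerSimonian–Laird random-effects
meta-analysis: `τ² = max(0, (Q − (k−1))/C)` from the fixed-effect
inverse-variance fit, pooled weights `1/(vᵢ + τ²)`, Wald CI. DL was
chosen as the standard moments estimator; it is isolated behind
`dersimonian_laird` and swappable. Per-SD coefficients are computed
within each subset *before* pooling.

The per-CpG frailty scan fits the same Model-1 mixed model per CpG with
the predictor scaled to 10%-unit *decreases* in methylation (so
hypomethylation-risk CpGs get positive coefficients), pools across
subsets, and applies Benjamini–Hochberg step-up FDR control across the
CpG list at q = 0.05. Note that BH adjusted values are monotone and
capped at 1 but *not* idempotent: re-adjusting adjusted values inflates
them, so the adjustment is applied exactly once per scan.

## Mortality models

* **Full cohort:** Cox proportional hazards, Efron tie handling, Newton
  iterations to precision 1e-9, Breslow baseline hazard retained for
  survival-probability prediction. Follow-up time starts at study entry;
  age is a covariate, not the timescale.
* **Case-cohort:** Barlow weighting. Subcohort members are at risk from
  time 0 with weight 1/α (α = subcohort sampling fraction); cases carry
  weight 1 at their own failure; cases outside the subcohort enter the
  risk set only just before their failure time (implemented by left
  truncation with an entry gap of 1e-6 years). The variance is a robust
  sandwich clustered on subject and is the default CI basis whenever
  weights differ from 1. Simulation shows the estimator recovers a true
  per-SD log HR of ln 2 with ~1% bias and ~92–95% CI coverage at
  n = 3000, α = 0.2.
* **Nested case-control:** maximum-likelihood logistic regression with
  Wald CIs; separation raises an explicit error.

Ties are handled by Efron's correction only (the lifelines
implementation); a Breslow option is not provided.

Rescaling to per-SD or per-k-unit increments multiplies the coefficient
and CI bounds by the unit ratio before exponentiation:
`HR_new = HR_old^(new/old)`. The meta-analysis of the two survival
subsets pools log hazard ratios row by row (per category, per unit, per
5-year AA, per 10%-unit FI, per SD).

## Predictive accuracy

* **Harrell's C** counts pairs comparable when the member with the
  strictly earlier observed time had an event; tied risks count 0.5,
  tied times are not comparable. The CI uses a Noether-type asymptotic
  normal SE from per-subject sums of the pair indicators (an
  infinitesimal-jackknife estimate of the U-statistic variance), clipped
  to [0, 1].
* **IPCW Brier curves** use Kaplan–Meier censoring weights: events by t
  weighted 1/G(T⁻), survivors past t weighted 1/G(t), subjects censored
  by t weight 0. Grid points where G reaches 0 (e.g. beyond the
  administrative-censoring horizon) are dropped with a warning. Survival
  predictions come from the fitted Cox model's Breslow baseline. Curves
  are apparent (in-sample) errors; no cross-validation is applied, and
  C-statistics are likewise apparent.
* **Time-dependent AUC** is the cumulative-cases / dynamic-controls
  estimator with IPCW on the cases; in the censoring-free limit it
  equals the binary AUC of the event-by-t indicator.
* **Binary AUC** is the midrank Mann–Whitney statistic, equal to the
  concordance of logistic predicted probabilities.

In the case-cohort subset, accuracy metrics are computed within the
random subcohort (a representative sample of the cohort, where standard
unweighted estimates apply); the nested case-control subset uses the
binary AUC.

## Synthetic-cohort generator

The generator emulates the *joint structure* the analyses assume, not any
particular cohort:

* Age ~ Uniform(50, 75); DNAm age = 10.4 + 0.82·age + N(0, 5.3²) years,
  calibrated so Spearman(age, DNAm age) ≈ 0.75 and the DNAm-age marginal
  mean/SD resemble a cohort of older adults.
* A single standard-normal latent risk factor loads on the ten CpG
  logits (±0.2, negative for hypo CpGs) and weakly (0.15) on the frailty
  liability, producing the weak positive score–FI rank correlation
  (~0.13) seen in population data, while AA (pure DNAm-age noise) stays
  uncorrelated with FI.
* Each of 34 deficits is Bernoulli with
  logit p = −1.55 + 0.03·(age − 50) + liability,
  liability ~ N(0, 0.68²) plus the latent term; this calibrates the FI
  to mean ≈ 0.25, SD ≈ 0.15. Deficit values are set missing completely
  at random at 5% to exercise the imputation path; the complete-data FI
  is retained as `fi_true`.
* CpG beta means (0.15–0.80 on the beta scale) and the weight vector
  give a continuous score mean ≈ −2.8, SD ≈ 0.53. Batch shifts
  (4 batches, SD 0.1 logit) act on CpG logits.
* Survival is Weibull proportional hazards (shape 1.1, scale 63 years)
  with log hazard linear in the z-scores of the three indicators —
  default per-SD log HRs (0.65, 0.31, 0.05) for (cont.MRscore, FI, AA),
  the joint-model magnitudes — plus 0.08 per year of age. Censoring is
  the minimum of exponential dropout (rate 0.01/year) and administrative
  censoring at 14 years, yielding ~22% deaths by year 14.

Design realizations: the case-cohort sampler includes every death plus an
independent-Bernoulli subcohort (weights 1/α for subcohort members, 1 for
outside cases); the nested case-control sampler draws controls without
replacement at a configurable ratio.

What the generator does **not** emulate: genome-wide probe structure
(only the ten score CpGs plus an optional extra block for the scan),
co-methylation beyond the single latent factor, informative censoring or
competing risks, graded (non-binary) deficits, measurement error in DNAm
age, and confounding between smoking/alcohol and methylation (lifestyle
covariates are generated independently). Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the pipeline on data satisfying its assumptions — not robustness to the
violations real cohort data may exhibit.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeded from
  configuration; identical config + seed reproduces byte-identical
  outputs, including written TSVs.
* Quantiles: linear interpolation; z-scores: ddof = 1; logistic /
  mixed-model CIs: Wald with z = 1.96; Rubin CIs use the t reference
  with Rubin's small-sample df, reverting to normal when the
  between-imputation variance is 0.
* Constant beta columns yield degenerate cutoffs with a warning;
  constant columns in correlation matrices yield NaN entries with a
  warning; zero-variance indicators requested with nonzero effects are
  rejected at config validation.
* Follow-up times are floored at 1e-8 years to keep them strictly
  positive; the Barlow entry gap (1e-6) is far smaller than any
  meaningful time difference at the simulated scale.

## Problem sizes

Default analysis runs use subsets of ~500–1000 subjects and 5 imputations;
calibration checks use n = 5000; the case-cohort validation experiment
uses 100 replicates of n = 3000. These sizes give Monte-Carlo error well
inside the tolerances asserted in the test suite while keeping a full run
of suite plus acceptance script in the low minutes on a single core.

## Known limitations

* Horvath DNAm age itself is an input column, never computed; leukocyte
  deconvolution is likewise upstream (proportions enter as covariates).
* Only Barlow weighting is implemented for case-cohort data (no
  Prentice/self-weighted variants), and only Efron tie handling for Cox
  models.
* The imputation model is first-order logistic; it will understate
  uncertainty for structured missingness.
* Apparent (in-sample) accuracy metrics overstate out-of-sample
  performance; cross-validated prediction-error curves are not
  implemented.
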