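"""Synthetic cohort generator.

Generates population-based cohorts of older adults with the joint
structure the downstream analyses assume: ten score CpGs (plus optional
extra CpGs for the per-CpG scan), a deficit panel feeding the frailty
index, DNA-methylation age, and mortality over a 14-year follow-up window,
together with the three sampling designs (full cohort, case-cohort with
oversampled deaths, nested case-control).

The generative model
--------------------
* Chronological age is uniform on ``age_range`` (50-75 years by default).
* DNAm age = intercept + slope * age + Gaussian noise; the defaults are
  calibrated so the age / DNAm-age Spearman correlation is about 0.75 and
  the marginal mean/SD resemble a cohort of 50-75 year olds.
* A single standard-normal latent "risk" factor couples the methylation
  score to frailty: it loads on each CpG on the logit scale (negative
  loadings for the hypomethylated CpGs) and, weakly, on the frailty
  liability, producing the weak positive score-FI correlation seen in
  population data (rank correlation roughly 0.1-0.2).
* Each of the 34 deficits is Bernoulli with
  logit p = base + age_gradient * (age - age_min) + liability, where the
  per-subject liability is Gaussian plus the latent-risk contribution.
  The defaults are calibrated so the frailty index has mean ~0.25 and SD
  ~0.15.  A configurable fraction of deficit values is set missing
  completely at random to exercise the imputation path.
* CpG betas are inverse-logit(mean + loading * latent + batch shift +
  noise), guaranteeing values strictly inside (0, 1).
* Survival times are Weibull proportional hazards with log hazard linear
  in the z-scores of the three indicators (cont.MRscore, FI, AA) plus
  age; observed time is the minimum of the event time, exponential
  dropout, and administrative censoring at 14 years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scores import MRSCORE_WEIGHTS, cont_mrscore

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "sample_case_cohort",
    "sample_nested_case_control",
]


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1 / (1 + np.exp(-x))


#: per-CpG beta means (calibrated so the continuous score mean is ~ -2.7,
#: near the Table-1-style population values) and latent-risk loadings on
#: the logit scale (negative for hypomethylated CpGs: higher latent risk
#: -> lower methylation -> higher risk score)
_DEFAULT_CPG_BETA_MEANS: dict[str, float] = {
    "cg01612140": 0.75,
    "cg05575921": 0.80,
    "cg06126421": 0.55,
    "cg08362785": 0.30,
    "cg10321156": 0.60,
    "cg14975410": 0.55,
    "cg19572487": 0.70,
    "cg23665802": 0.55,
    "cg24704287": 0.15,
    "cg25983901": 0.25,
}


def _default_cpg_means() -> tuple[float, ...]:
    return tuple(_logit(np.array(list(_DEFAULT_CPG_BETA_MEANS.values()))))


def _default_loadings() -> tuple[float, ...]:
    return tuple(
        0.2 if MRSCORE_WEIGHTS[c] > 0 else -0.2 for c in _DEFAULT_CPG_BETA_MEANS
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All generating values of the synthetic cohort.

    Effect sizes ``log_hr_per_sd`` are (cont.MRscore, FI, AA), defaulting
    to the joint-model magnitudes of roughly HR 1.9 / 1.4 / 1.05 per SD.
    """

    n_subjects: int = 1000
    seed: int = 0
    age_range: tuple[float, float] = (50.0, 75.0)
    # DNAm age model (years)
    dnam_age_slope: float = 0.82
    dnam_age_intercept: float = 10.4
    dnam_age_noise_sd: float = 5.3
    # deficit panel
    n_deficits: int = 34
    deficit_base_logit: float = -1.55
    deficit_age_gradient: float = 0.03  # per year of age
    deficit_liability_sd: float = 0.68
    deficit_missing_rate: float = 0.05
    # score CpGs (logit scale)
    cpg_means: tuple[float, ...] = field(default_factory=_default_cpg_means)
    cpg_sds: tuple[float, ...] = (0.35,) * 10
    latent_risk_loading: tuple[float, ...] = field(default_factory=_default_loadings)
    frailty_latent_loading: float = 0.15
    # survival model
    log_hr_per_sd: tuple[float, float, float] = (0.65, 0.31, 0.05)
    log_hr_per_year_age: float = 0.08
    baseline_hazard_shape: float = 1.1
    baseline_hazard_scale: float = 63.0
    admin_censor_years: float = 14.0
    dropout_rate: float = 0.01  # per year
    # batches and designs
    n_batches: int = 4
    batch_shift_sd: float = 0.10
    subcohort_fraction: float = 0.1
    control_ratio: int = 1
    # optional extra CpGs for the per-CpG frailty scan
    n_extra_cpgs: int = 0
    extra_cpg_fi_loading: float = 0.0

    def validate(self) -> None:
        numeric = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            numeric.extend(np.atleast_1d(v).astype(float))
        if not np.all(np.isfinite(numeric)):
            raise ValueError("non-finite values in simulation config")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")
        for name in ("deficit_missing_rate", "subcohort_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.cpg_means) != 10 or len(self.cpg_sds) != 10 or len(self.latent_risk_loading) != 10:
            raise ValueError("cpg_means, cpg_sds, latent_risk_loading must have length 10")
        # a requested effect on a degenerate (zero-variance) indicator is
        # uninterpretable: the z-score is undefined
        if self.log_hr_per_sd[2] != 0 and self.dnam_age_noise_sd == 0:
            raise ValueError("nonzero AA effect requested but AA has zero variance")
        if self.log_hr_per_sd[1] != 0 and self.deficit_liability_sd == 0 and self.deficit_age_gradient == 0:
            raise ValueError("nonzero FI effect requested but FI has (near) zero variance")
        if self.log_hr_per_sd[0] != 0 and all(s == 0 for s in self.cpg_sds) and all(
            l == 0 for l in self.latent_risk_loading
        ):
            raise ValueError("nonzero score effect requested but the score has zero variance")


@dataclass
class SimulatedCohort:
    """A simulated cohort with all components keyed by subject ID.

    ``cohort`` carries demographics, covariates, batch, follow-up time and
    event indicator (plus the generator's own FI/AA, columns ``fi_true``
    and ``aa_true``, computed from the complete deficit panel and the
    DNAm-age noise).  ``betas`` is CpG x sample; ``deficits`` is subject x deficit
    with NaN for missing.  ``true_parameters`` records every generating
    value.
    """

    cohort: pd.DataFrame
    betas: pd.DataFrame
    deficits: pd.DataFrame
    dnam_age: pd.Series
    true_parameters: dict
    weights: pd.Series | None = None

    @property
    def subjects(self) -> pd.Index:
        return self.cohort.index


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    sex = rng.integers(0, 2, n)  # 1 = male
    batch = rng.integers(0, config.n_batches, n)
    smoking = rng.choice([0, 1, 2], size=n, p=[0.45, 0.35, 0.20])  # never/former/current
    alcohol = np.round(rng.lognormal(1.5, 0.9, n), 1)  # g/day
    # leukocyte composition: granulocyte / lymphocyte / monocyte proportions
    cells = rng.dirichlet([12.0, 6.0, 2.0], size=n)

    dnam_age = (
        config.dnam_age_intercept
        + config.dnam_age_slope * age
        + rng.normal(0, config.dnam_age_noise_sd, n)
    )

    latent = rng.normal(0, 1, n)

    # --- CpG betas ---
    cpg_ids = list(MRSCORE_WEIGHTS)
    batch_shifts = rng.normal(0, config.batch_shift_sd, (config.n_batches, len(cpg_ids)))
    logits = (
        np.asarray(config.cpg_means)[None, :]
        + latent[:, None] * np.asarray(config.latent_risk_loading)[None, :]
        + batch_shifts[batch]
        + rng.normal(0, 1, (n, len(cpg_ids))) * np.asarray(config.cpg_sds)[None, :]
    )
    betas = _expit(logits)

    extra_ids = []
    if config.n_extra_cpgs > 0:
        extra_ids = [f"cgE{i:06d}" for i in range(config.n_extra_cpgs)]
        frailty_liab_loading = config.extra_cpg_fi_loading
        extra_means = rng.uniform(_logit(0.2), _logit(0.8), config.n_extra_cpgs)
        extra_logits = (
            extra_means[None, :]
            + frailty_liab_loading * latent[:, None]
            + rng.normal(0, 0.35, (n, config.n_extra_cpgs))
        )
        betas = np.column_stack([betas, _expit(extra_logits)])
    beta_mat = pd.DataFrame(betas.T, index=cpg_ids + extra_ids, columns=ids)
    beta_mat.index.name = "cpg_id"

    # --- deficits and frailty index ---
    liability = (
        rng.normal(0, config.deficit_liability_sd, n)
        + config.frailty_latent_loading * latent
    )
    p_deficit = _expit(
        config.deficit_base_logit
        + config.deficit_age_gradient * (age - lo)
        + liability
    )
    deficits_complete = (
        rng.random((n, config.n_deficits)) < p_deficit[:, None]
    ).astype(float)
    fi_true = deficits_complete.mean(axis=1)
    deficits = deficits_complete.copy()
    if config.deficit_missing_rate > 0:
        miss = rng.random(deficits.shape) < config.deficit_missing_rate
        deficits[miss] = np.nan
    deficit_cols = [f"deficit_{i + 1:02d}" for i in range(config.n_deficits)]
    deficit_panel = pd.DataFrame(deficits, index=ids, columns=deficit_cols)

    # --- survival ---
    score = cont_mrscore(beta_mat).to_numpy()
    aa = dnam_age - (config.dnam_age_intercept + config.dnam_age_slope * age)

    def _z(x):
        sd = np.std(x, ddof=1)
        return np.zeros_like(x) if sd == 0 else (x - np.mean(x)) / sd

    b_score, b_fi, b_aa = config.log_hr_per_sd
    eta = (
        b_score * _z(score)
        + b_fi * _z(fi_true)
        + b_aa * _z(aa)
        + config.log_hr_per_year_age * (age - age.mean())
    )
    u = rng.uniform(size=n)
    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    t_event = scale * (-np.log(u) / np.exp(eta)) ** (1 / shape)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1 / config.dropout_rate, n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-8)  # strictly positive follow-up

    cohort = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch": batch,
            "smoking": smoking,
            "alcohol": alcohol,
            "gran": cells[:, 0],
            "lymph": cells[:, 1],
            "mono": cells[:, 2],
            "dnam_age": dnam_age,
            "aa_true": aa,
            "fi_true": fi_true,
            "time": time,
            "event": event,
        },
        index=ids,
    )
    return SimulatedCohort(
        cohort=cohort,
        betas=beta_mat,
        deficits=deficit_panel,
        dnam_age=cohort["dnam_age"],
        true_parameters=dataclasses.asdict(config),
    )


def _subset(full: SimulatedCohort, keep: pd.Index, extra_cols: pd.DataFrame,
            weights: pd.Series | None = None) -> SimulatedCohort:
    cohort = full.cohort.loc[keep].join(extra_cols)
    return SimulatedCohort(
        cohort=cohort,
        betas=full.betas[keep],
        deficits=full.deficits.loc[keep],
        dnam_age=full.dnam_age.loc[keep],
        true_parameters=dict(full.true_parameters),
        weights=weights,
    )


def sample_case_cohort(
    full: SimulatedCohort,
    subcohort_fraction: float | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Case-cohort sample: all deaths plus a random subcohort.

    Each subject enters the subcohort independently with probability
    ``subcohort_fraction``.  Design weights follow the Barlow convention:
    subcohort members 1/fraction, cases outside the subcohort 1.  The
    returned cohort table gains boolean ``subcohort`` and float ``weight``
    columns (also exposed as ``.weights``).
    """
    frac = full.true_parameters["subcohort_fraction"] if subcohort_fraction is None else subcohort_fraction
    if not 0 < frac <= 1:
        raise ValueError("subcohort fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    in_sub = pd.Series(rng.random(len(full.subjects)) < frac, index=full.subjects)
    if not in_sub.any():
        raise ValueError("subcohort is empty; increase the fraction")
    cases = full.cohort["event"] == 1
    keep = full.subjects[in_sub | cases]
    weight = pd.Series(1.0, index=keep, name="weight")
    weight[in_sub.loc[keep]] = 1.0 / frac
    extra = pd.DataFrame({"subcohort": in_sub.loc[keep], "weight": weight})
    out = _subset(full, keep, extra, weights=weight)
    out.true_parameters["realized_subcohort_fraction"] = float(in_sub.mean())
    out.true_parameters["subcohort_fraction"] = float(frac)
    return out


def sample_nested_case_control(
    full: SimulatedCohort,
    control_ratio: int | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Nested case-control sample: all cases plus sampled controls.

    Controls are drawn without replacement from non-cases at
    ``control_ratio`` controls per case; a binary outcome column ``case``
    is added.
    """
    ratio = full.true_parameters["control_ratio"] if control_ratio is None else control_ratio
    cases = full.subjects[full.cohort["event"] == 1]
    noncases = full.subjects[full.cohort["event"] == 0]
    n_controls = int(round(ratio * len(cases)))
    if n_controls > len(noncases):
        raise ValueError(
            f"insufficient controls: need {n_controls}, have {len(noncases)}"
        )
    rng = np.random.default_rng(seed)
    controls = pd.Index(rng.choice(noncases, size=n_controls, replace=False))
    keep = cases.append(controls)
    case_col = pd.Series(0, index=keep, name="case")
    case_col.loc[cases] = 1
    return _subset(full, keep, case_col.to_frame())
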