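"""End-to-end orchestration over the three study subsets.

Builds three synthetic subsets (full cohort; case-cohort with oversampled
deaths; nested case-control), computes the indicator panel for each, and
runs the analysis ladder: frailty-association mixed models with
random-effects meta-analysis, the per-CpG frailty scan with BH-FDR,
mortality models per design, and the predictive-accuracy comparison.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .accuracy import binary_auc, brier_curve, harrell_c, time_dependent_auc
from .frailty import frailty_index, impute_deficits
from .scores import build_score_panel, zscore
from .simulate import (
    SimulatedCohort,
    SimulationConfig,
    sample_case_cohort,
    sample_nested_case_control,
    simulate_cohort,
)
from .stats import (
    EffectEstimate,
    bh_adjust,
    dersimonian_laird,
    fit_random_intercept_lm,
    pool_rubin,
)
from .survival import fit_case_cohort_cox, fit_cox, fit_logistic, rescale_hr

logger = logging.getLogger("methylsurv")

__all__ = [
    "AnalysisConfig",
    "Subset",
    "build_subsets",
    "run_frailty_association",
    "run_cpg_frailty_scan",
    "run_mortality_analysis",
    "run_accuracy_comparison",
    "run_all",
]

_Z95 = 1.959963984540054


@dataclass
class AnalysisConfig:
    """Configuration of the full pipeline.

    Covariate ladders are configuration, not code: Model 1 adjusts for
    demographics and leukocyte composition, Model 2 adds lifestyle
    covariates, Model 3 enters both methylomic predictors jointly.
    """

    seed: int = 0
    n_subjects: tuple[int, int, int] = (1000, 1000, 1000)
    subcohort_fraction: float = 0.15
    control_ratio: int = 1
    m_imputations: int = 5
    impute_fi: bool = True
    fdr_q: float = 0.05
    time_grid: tuple[float, ...] = tuple(np.arange(1.0, 13.1, 1.0))
    assoc_model1: tuple[str, ...] = ("age", "sex", "gran", "mono")
    assoc_model2: tuple[str, ...] = ("age", "sex", "gran", "mono", "smoking", "alcohol")
    mortality_covariates: tuple[str, ...] = ("age", "sex")
    simulation: SimulationConfig | None = None

    def base_simulation(self) -> SimulationConfig:
        return self.simulation if self.simulation is not None else SimulationConfig()


@dataclass
class Subset:
    """One analysis subset: design, data, indicator panel."""

    name: str
    design: str  # "cohort" | "casecohort" | "ncc"
    sim: SimulatedCohort
    panel: pd.DataFrame
    fi_imputations: pd.DataFrame | None = None  # FI per subject per imputation

    @property
    def data(self) -> pd.DataFrame:
        """Cohort table joined with the indicator panel."""
        return self.sim.cohort.join(self.panel, rsuffix="_panel")


def _make_subset(name: str, design: str, base: SimulationConfig, n: int, seed: int,
                 config: AnalysisConfig) -> Subset:
    sim_cfg = dataclasses.replace(base, n_subjects=n, seed=seed)
    full = simulate_cohort(sim_cfg)
    if design == "casecohort":
        sampled = sample_case_cohort(full, config.subcohort_fraction, seed=seed + 1000)
    elif design == "ncc":
        sampled = sample_nested_case_control(full, config.control_ratio, seed=seed + 1000)
    elif design == "cohort":
        sampled = full
    else:
        raise ValueError(f"unknown design {design!r}")

    fi_imp = None
    if config.impute_fi and sampled.deficits.isna().to_numpy().any():
        imp = impute_deficits(
            sampled.deficits,
            sampled.cohort[["age", "sex"]],
            m=config.m_imputations,
            seed=seed + 2000,
        )
        fi_imp = imp.frailty_indices()
        fi = fi_imp.mean(axis=1)
    else:
        fi = frailty_index(sampled.deficits, denominator="observed")
    panel = build_score_panel(sampled.cohort, sampled.betas, fi=fi)
    logger.info(
        "subset %s (%s): n=%d, events=%d", name, design,
        len(sampled.cohort), int(sampled.cohort["event"].sum()),
    )
    return Subset(name=name, design=design, sim=sampled, panel=panel, fi_imputations=fi_imp)


def build_subsets(config: AnalysisConfig) -> dict[str, Subset]:
    """Generate the three analysis subsets from independent cohorts."""
    base = config.base_simulation()
    designs = [("I", "cohort"), ("II", "casecohort"), ("III", "ncc")]
    return {
        name: _make_subset(name, design, base, config.n_subjects[i], config.seed + i, config)
        for i, (name, design) in enumerate(designs)
    }


# ---------------------------------------------------------------------------
# frailty association (Table-2-style)
# ---------------------------------------------------------------------------

_INDICATORS = {
    "mrscore": "mrscore_z",
    "cont_mrscore": "cont_mrscore_z",
    "age_acceleration": "age_acceleration_z",
}


def _fit_fi_models(subset: Subset, predictors: list[str], covariates: tuple[str, ...],
                   focal: str) -> EffectEstimate:
    """Random-intercept fit(s) of FI (%) on z-scored predictors.

    With multiply imputed FI the model is fitted per completed dataset and
    pooled by Rubin's rules.
    """
    data = subset.data
    X = data[list(dict.fromkeys(predictors + list(covariates)))]
    groups = data["batch"]
    if subset.fi_imputations is not None:
        ests = []
        for col in subset.fi_imputations:
            y = subset.fi_imputations[col] * 100.0
            eff, _ = fit_random_intercept_lm(y, X, groups)
            ests.append(eff[focal])
        return pool_rubin(ests)
    y = data["fi"] * 100.0
    eff, _ = fit_random_intercept_lm(y, X, groups)
    return eff[focal]


def run_frailty_association(subsets: dict[str, Subset], config: AnalysisConfig) -> pd.DataFrame:
    """Associations of the methylomic indicators with FI (% units per SD).

    Models 1 and 2 enter one indicator at a time; Model 3 enters the
    mortality score and AA jointly.  Per-subset estimates are pooled by
    DerSimonian-Laird random-effects meta-analysis.
    """
    rows = []
    plans: list[tuple[str, str, list[str]]] = []
    for ind, zcol in _INDICATORS.items():
        plans.append((ind, "model1", [zcol]))
        plans.append((ind, "model2", [zcol]))
    for ind in ("mrscore", "cont_mrscore"):
        plans.append((ind, "model3", [_INDICATORS[ind], "age_acceleration_z"]))
        plans.append(("age_acceleration|" + ind, "model3",
                      ["age_acceleration_z", _INDICATORS[ind]]))

    for ind, model, predictors in plans:
        covs = config.assoc_model1 if model == "model1" else config.assoc_model2
        focal = predictors[0]
        per_subset = {}
        for name, subset in subsets.items():
            est = _fit_fi_models(subset, predictors, covs, focal)
            per_subset[name] = est
            rows.append(_effect_row(name, ind, model, est))
        pooled = dersimonian_laird(list(per_subset.values()))
        rows.append(_pooled_row("overall", ind, model, pooled))
    return pd.DataFrame(rows)


def _effect_row(subset, indicator, model, e: EffectEstimate) -> dict:
    return {
        "subset": subset, "indicator": indicator, "model": model,
        "coefficient": e.coefficient, "se": e.se,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p_value, "n": e.n,
        "tau2": np.nan,
    }


def _pooled_row(subset, indicator, model, p) -> dict:
    return {
        "subset": subset, "indicator": indicator, "model": model,
        "coefficient": p.coefficient, "se": p.se,
        "ci_low": p.ci_low, "ci_high": p.ci_high, "p": p.p_value,
        "n": np.nan, "tau2": p.tau2,
    }


# ---------------------------------------------------------------------------
# per-CpG frailty scan
# ---------------------------------------------------------------------------

def run_cpg_frailty_scan(subsets: dict[str, Subset], cpg_list: list[str],
                         config: AnalysisConfig) -> pd.DataFrame:
    """Per-CpG FI associations, meta-analyzed and BH-FDR flagged.

    Coefficients are reported as FI % units per 10%-unit *decrease* in
    methylation beta (the sign convention of hypomethylation-risk
    reporting).  CpGs absent from a subset's beta matrix are skipped with
    a ``skipped`` flag.
    """
    if not cpg_list:
        return pd.DataFrame(
            columns=["cpg_id", "coefficient", "se", "ci_low", "ci_high",
                     "p", "p_adjusted", "significant", "k", "skipped"]
        )
    rows = []
    for cpg in cpg_list:
        ests = []
        for subset in subsets.values():
            if cpg not in subset.sim.betas.index:
                continue
            data = subset.data
            # per 10%-unit decrease in beta
            x = -subset.sim.betas.loc[cpg].reindex(data.index) * 10.0
            X = pd.concat([x.rename(cpg), data[list(config.assoc_model1)]], axis=1)
            if subset.fi_imputations is not None:
                per_imp = []
                for col in subset.fi_imputations:
                    eff, _ = fit_random_intercept_lm(
                        subset.fi_imputations[col] * 100.0, X, data["batch"])
                    per_imp.append(eff[cpg])
                ests.append(pool_rubin(per_imp))
            else:
                eff, _ = fit_random_intercept_lm(data["fi"] * 100.0, X, data["batch"])
                ests.append(eff[cpg])
        if len(ests) < 2:
            rows.append({"cpg_id": cpg, "skipped": True})
            continue
        p = dersimonian_laird(ests)
        rows.append({
            "cpg_id": cpg, "coefficient": p.coefficient, "se": p.se,
            "ci_low": p.ci_low, "ci_high": p.ci_high, "p": p.p_value,
            "k": p.k, "skipped": False,
        })
    out = pd.DataFrame(rows)
    tested = out.index[~out["skipped"].astype(bool)]
    out["p_adjusted"] = np.nan
    out["significant"] = False
    if len(tested):
        adj, rej = bh_adjust(out.loc[tested, "p"].to_numpy(), q=config.fdr_q)
        out.loc[tested, "p_adjusted"] = adj
        out.loc[tested, "significant"] = rej
    return out


# ---------------------------------------------------------------------------
# mortality models (Table-3-style)
# ---------------------------------------------------------------------------

def _fit_design(subset: Subset, covariates: list[str], data: pd.DataFrame):
    if subset.design == "cohort":
        return fit_cox(data, "time", "event", covariates)
    if subset.design == "casecohort":
        return fit_case_cohort_cox(
            data, "time", "event", covariates,
            subcohort_col="subcohort",
            sampling_fraction=subset.sim.true_parameters["subcohort_fraction"],
        )
    return fit_logistic(data, "case", covariates)


def _mortality_rows(subset: Subset, config: AnalysisConfig) -> list[dict]:
    data = subset.data.copy()
    rows = []
    covs = list(config.mortality_covariates)
    sds = {
        "mrscore": data["mrscore"].std(ddof=1),
        "cont_mrscore": data["cont_mrscore"].std(ddof=1),
        "age_acceleration": data["age_acceleration"].std(ddof=1),
        "fi": data["fi"].std(ddof=1),
    }

    # categorized score, Model 1
    for cat, col in (("1", "mrs_1"), ("2-5", "mrs_2_5"), (">5", "mrs_gt5")):
        data[col] = (data["mrscore_category"] == cat).astype(float)
    cat_cols = ["mrs_1", "mrs_2_5", "mrs_gt5"]
    if (data[cat_cols].sum() > 0).all() and (data["mrscore_category"] == "0").any():
        fit = _fit_design(subset, cat_cols + covs, data)
        for cat, col in (("1", "mrs_1"), ("2-5", "mrs_2_5"), (">5", "mrs_gt5")):
            rows.append(_hr_row(subset, "mrscore=" + cat, "model1", fit, col, 1.0, sds))

    # per-unit / per-k-unit / per-SD, Model 1 (one indicator at a time)
    singles = [
        ("cont_mrscore", "per 1 unit", 1.0),
        ("cont_mrscore", "per SD", sds["cont_mrscore"]),
        ("mrscore", "per SD", sds["mrscore"]),
        ("age_acceleration", "per 5 years", 5.0),
        ("age_acceleration", "per SD", sds["age_acceleration"]),
        ("fi", "per 10%", 0.1),
        ("fi", "per SD", sds["fi"]),
    ]
    fits1 = {}
    for term in ("cont_mrscore", "mrscore", "age_acceleration", "fi"):
        fits1[term] = _fit_design(subset, [term] + covs, data)
    for term, unit, ratio in singles:
        rows.append(_hr_row(subset, term + " (" + unit + ")", "model1", fits1[term], term, ratio, sds))

    # Model 2: the three indicators jointly
    joint = ["cont_mrscore", "fi", "age_acceleration"]
    fit2 = _fit_design(subset, joint + covs, data)
    for term, unit, ratio in [
        ("cont_mrscore", "per 1 unit", 1.0),
        ("cont_mrscore", "per SD", sds["cont_mrscore"]),
        ("age_acceleration", "per 5 years", 5.0),
        ("age_acceleration", "per SD", sds["age_acceleration"]),
        ("fi", "per 10%", 0.1),
        ("fi", "per SD", sds["fi"]),
    ]:
        rows.append(_hr_row(subset, term + " (" + unit + ")", "model2", fit2, term, ratio, sds))
    return rows


def _hr_row(subset: Subset, label: str, model: str, fit, term: str, ratio: float, sds) -> dict:
    coef = float(fit.summary.loc[term, "coef"]) * ratio
    se = float(fit.summary.loc[term, "se"]) * ratio
    hr, lo, hi = rescale_hr(*fit.hazard_ratio(term), ratio)
    return {
        "subset": subset.name, "design": subset.design, "label": label,
        "model": model, "coef": coef, "se": se,
        "hr": hr, "ci_low": lo, "ci_high": hi,
        "p": float(fit.summary.loc[term, "p"]),
        "n": fit.n, "events": fit.n_events,
    }


def run_mortality_analysis(subsets: dict[str, Subset], config: AnalysisConfig) -> pd.DataFrame:
    """Mortality models per design, plus meta-analysis of subsets I and II.

    Subset I uses Cox PH, subset II the Barlow-weighted case-cohort Cox,
    and subset III logistic regression (ORs).  Effects are reported per
    category, per unit, per 5-year AA, per 10%-unit FI, and per SD; the
    per-SD scaling uses each subset's own sample SD before pooling.
    """
    rows = []
    for subset in subsets.values():
        rows.extend(_mortality_rows(subset, config))
    out = pd.DataFrame(rows)

    pooled_rows = []
    meta_subsets = [s for s in ("I", "II") if s in subsets]
    if len(meta_subsets) >= 2:
        for (label, model), grp in out[out["subset"].isin(meta_subsets)].groupby(
            ["label", "model"], sort=False
        ):
            ests = [
                EffectEstimate(term=label, coefficient=r["coef"], se=r["se"],
                               ci_low=0, ci_high=0, p_value=r["p"], n=int(r["n"]))
                for _, r in grp.iterrows()
            ]
            p = dersimonian_laird(ests)
            pooled_rows.append({
                "subset": "I+II (meta)", "design": "meta", "label": label,
                "model": model, "coef": p.coefficient, "se": p.se,
                "hr": float(np.exp(p.coefficient)),
                "ci_low": float(np.exp(p.ci_low)),
                "ci_high": float(np.exp(p.ci_high)),
                "p": p.p_value, "n": int(grp["n"].sum()),
                "events": int(grp["events"].sum()),
            })
    return pd.concat([out, pd.DataFrame(pooled_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# predictive accuracy (Table-4-style)
# ---------------------------------------------------------------------------

PREDICTOR_SETS: dict[str, list[str]] = {
    "age": ["age"],
    "dnam_age": ["dnam_age"],
    "dnam_age + age": ["dnam_age", "age"],
    "age_acceleration": ["age_acceleration"],
    "age_acceleration + age": ["age_acceleration", "age"],
    "cont_mrscore": ["cont_mrscore"],
    "cont_mrscore + age": ["cont_mrscore", "age"],
    "fi": ["fi"],
    "fi + age": ["fi", "age"],
    "cont_mrscore + fi": ["cont_mrscore", "fi"],
    "cont_mrscore + fi + age": ["cont_mrscore", "fi", "age"],
}


def run_accuracy_comparison(subsets: dict[str, Subset], config: AnalysisConfig,
                            curves: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harrell's C / C-index per predictor set, with optional curves.

    Subsets with survival outcomes use Cox linear predictors as the risk
    score (subset II restricted to its random subcohort, where standard
    unweighted Cox applies); the nested case-control subset uses logistic
    predicted probabilities and the binary AUC.  Returns (summary, curves)
    where curves holds Brier(t) and AUC(t) rows for the full-cohort
    subset.
    """
    summary_rows = []
    curve_frames = []
    grid = np.asarray(config.time_grid, float)
    for subset in subsets.values():
        data = subset.data
        if subset.design == "casecohort":
            data = data[data["subcohort"].astype(bool)]
        for label, covs in PREDICTOR_SETS.items():
            if subset.design == "ncc":
                fit = fit_logistic(data, "case", covs)
                risk = fit.model.predict()
                auc = binary_auc(data["case"], risk)
                summary_rows.append({
                    "subset": subset.name, "label": label, "metric": "binary_auc",
                    "estimate": auc, "ci_low": np.nan, "ci_high": np.nan,
                })
                continue
            fit = fit_cox(data, "time", "event", covs)
            risk = fit.model.predict_log_partial_hazard(data)
            cres = harrell_c(data["time"], data["event"], risk)
            summary_rows.append({
                "subset": subset.name, "label": label, "metric": "harrell_c",
                "estimate": cres.c, "ci_low": cres.ci_low, "ci_high": cres.ci_high,
            })
            if curves and subset.design == "cohort":
                sp = fit.predict_survival(data, grid)
                b = brier_curve(grid, data["time"], data["event"], sp)
                a = time_dependent_auc(
                    b.index.to_numpy(), data["time"], data["event"], risk
                )
                cf = pd.DataFrame({
                    "subset": subset.name, "label": label,
                    "time": b.index, "brier": b.to_numpy(),
                    "auc_t": a.reindex(b.index).to_numpy(),
                })
                curve_frames.append(cf)
    summary = pd.DataFrame(summary_rows)
    curves_df = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["subset", "label", "time", "brier", "auc_t"])
    )
    return summary, curves_df


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_all(config: AnalysisConfig, out_dir: str | Path | None = None,
            cpg_list: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Run the full pipeline; optionally write TSV result tables."""
    subsets = build_subsets(config)
    results = {
        "frailty_association": run_frailty_association(subsets, config),
    }
    if cpg_list is None and config.base_simulation().n_extra_cpgs > 0:
        cpg_list = [c for c in subsets["I"].sim.betas.index if c.startswith("cgE")]
    if cpg_list:
        results["cpg_frailty_scan"] = run_cpg_frailty_scan(subsets, cpg_list, config)
    results["mortality"] = run_mortality_analysis(subsets, config)
    acc_summary, acc_curves = run_accuracy_comparison(subsets, config)
    results["accuracy_summary"] = acc_summary
    results["accuracy_curves"] = acc_curves
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in results.items():
            io.write_table(table.round(10), out / f"{name}.tsv")
        logger.info("results written to %s", out)
    return results
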