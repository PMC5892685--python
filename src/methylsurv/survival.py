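"""Mortality models for the three sampling designs.

* Full cohort: Cox proportional hazards (Efron tie handling).
* Case-cohort (all deaths plus a random subcohort): weighted Cox partial
  likelihood in the Barlow scheme — subcohort members carry weight
  1/(sampling fraction) while at risk, cases carry weight 1 at their own
  failure, and cases outside the subcohort enter the risk set only just
  before their failure time.  A cluster-robust sandwich variance is the
  default CI basis whenever weights differ from 1.
* Nested case-control: maximum-likelihood logistic regression.

Effects are reported as hazard/odds ratios and can be rescaled to per-SD
or per-k-unit increments: HR_new = HR_old ** (new units / old units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "SurvivalFit",
    "fit_cox",
    "fit_case_cohort_cox",
    "fit_logistic",
    "rescale_effect",
    "rescale_hr",
]

_Z95 = sps.norm.ppf(0.975)

#: gap used to enter non-subcohort cases into the risk set just before
#: their failure time (Barlow late entry)
_ENTRY_EPS = 1e-6


@dataclass
class SurvivalFit:
    """A fitted mortality model (log-hazard or log-odds scale).

    ``summary`` has one row per term with columns coef, se, hr, ci_low,
    ci_high, p.  ``se`` is robust (sandwich) whenever weights were used.
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    kind: str  # "cox" | "case_cohort_cox" | "logistic"
    ties: str | None = "efron"
    weighted: bool = False
    model: object = field(default=None, repr=False)

    def hazard_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.summary.loc[term]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])

    def predict_survival(self, X: pd.DataFrame, times) -> pd.DataFrame:
        """S(t|x) on a time grid (rows = grid times, columns = subjects).

        Uses the Breslow baseline hazard of the fitted Cox model; for the
        logistic model survival prediction is undefined.
        """
        if self.kind == "logistic":
            raise ValueError("survival curves are undefined for logistic fits")
        return self.model.predict_survival_function(X, times=np.asarray(times, float))


def _summary_from_lifelines(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return out


def fit_cox(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    weights_col: str | None = None,
    entry_col: str | None = None,
    cluster_col: str | None = None,
    robust: bool | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Breslow baseline).

    Robust (sandwich) standard errors are used automatically when weights
    are supplied.  Raises on zero events or non-convergence (e.g. monotone
    likelihood under perfect separation).
    """
    cols = [duration_col, event_col] + list(covariates)
    for extra in (weights_col, entry_col, cluster_col):
        if extra:
            cols.append(extra)
    df = data[cols].dropna()
    if (df[duration_col] <= 0).any():
        raise ValueError("durations must be positive")
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    X = df[list(covariates)].to_numpy()
    if np.linalg.matrix_rank(X) < len(covariates):
        raise ValueError(f"collinear covariates among {covariates}")
    if robust is None:
        robust = weights_col is not None
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                formula=" + ".join(covariates),
                weights_col=weights_col,
                entry_col=entry_col,
                cluster_col=cluster_col,
                robust=robust,
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model failed to converge (possible separation): {err}"
        ) from err
    return SurvivalFit(
        summary=_summary_from_lifelines(cph),
        n=df[cluster_col].nunique() if cluster_col else len(df),
        n_events=n_events,
        kind="cox",
        weighted=weights_col is not None,
        model=cph,
    )


def fit_case_cohort_cox(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    subcohort_col: str = "subcohort",
    sampling_fraction: float | None = None,
    weight_col: str | None = "weight",
) -> SurvivalFit:
    """Barlow-weighted Cox fit for a case-cohort sample.

    Requires a boolean subcohort flag and either the subcohort sampling
    fraction alpha or a design-weight column from which it is inferred
    (subcohort weight = 1/alpha).  Row expansion implements the Barlow
    scheme: subcohort members are at risk from 0 with weight 1/alpha
    (cases switching to weight 1 at failure); non-subcohort cases enter
    just before their failure with weight 1.  The sandwich variance is
    clustered on subject.
    """
    df = data.dropna(subset=[duration_col, event_col, subcohort_col] + list(covariates))
    if sampling_fraction is None:
        if weight_col is None or weight_col not in df:
            raise ValueError("need sampling_fraction or a design-weight column")
        w_sub = df.loc[df[subcohort_col].astype(bool), weight_col]
        if w_sub.empty:
            raise ValueError("no subcohort members present")
        sampling_fraction = float(1.0 / w_sub.iloc[0])
    if not 0 < sampling_fraction <= 1:
        raise ValueError(f"implied sampling fraction {sampling_fraction} not in (0, 1]")
    alpha_w = 1.0 / sampling_fraction

    rows = []
    for subj, r in df.iterrows():
        t = float(r[duration_col])
        ev = int(r[event_col])
        sub = bool(r[subcohort_col])
        covs = tuple(r[c] for c in covariates)
        if sub and ev:
            if t > _ENTRY_EPS:
                rows.append((subj, 0.0, t - _ENTRY_EPS, 0, alpha_w) + covs)
            rows.append((subj, t - _ENTRY_EPS, t, 1, 1.0) + covs)
        elif sub:
            rows.append((subj, 0.0, t, 0, alpha_w) + covs)
        elif ev:
            rows.append((subj, t - _ENTRY_EPS, t, 1, 1.0) + covs)
        # non-subcohort non-cases contribute nothing
    long = pd.DataFrame(
        rows, columns=["__id__", "__entry__", "__stop__", "__event__", "__w__"] + list(covariates)
    )
    fit = fit_cox(
        long,
        duration_col="__stop__",
        event_col="__event__",
        covariates=list(covariates),
        weights_col="__w__",
        entry_col="__entry__",
        cluster_col="__id__",
    )
    fit.kind = "case_cohort_cox"
    fit.n = df.shape[0]
    fit.n_events = int(df[event_col].sum())
    return fit


def fit_logistic(
    data: pd.DataFrame,
    outcome_col: str,
    covariates: list[str],
) -> SurvivalFit:
    """Maximum-likelihood logistic regression with Wald CIs (log-odds form)."""
    df = data[[outcome_col] + list(covariates)].dropna()
    y = df[outcome_col]
    if set(y.unique()) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(df[list(covariates)], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"collinear covariates among {covariates}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False)
    except Exception as err:
        raise RuntimeError(f"logistic fit failed (possible separation): {err}") from err
    if not np.isfinite(res.bse).all() or np.abs(res.params.drop("const")).max() > 15:
        raise RuntimeError(
            "logistic fit did not converge to a finite solution "
            "(possible perfect separation); diverging terms: "
            + ", ".join(res.params.drop("const").abs().nlargest(3).index)
        )
    summary = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "hr": np.exp(res.params),
            "ci_low": np.exp(res.params - _Z95 * res.bse),
            "ci_high": np.exp(res.params + _Z95 * res.bse),
            "p": res.pvalues,
        }
    ).drop(index="const")
    summary.index.name = "term"
    return SurvivalFit(
        summary=summary,
        n=len(df),
        n_events=int(y.sum()),
        kind="logistic",
        ties=None,
        model=res,
    )


def rescale_hr(hr: float, ci_low: float, ci_high: float, ratio: float) -> tuple[float, float, float]:
    """Re-express a hazard/odds ratio per a different predictor increment.

    ``ratio`` is (new increment) / (old increment) in predictor units, so
    an HR per unit becomes per SD via ratio = SD.  On the log scale the
    coefficient and CI bounds are multiplied by the ratio, hence
    HR_new = HR_old ** ratio.
    """
    if ratio <= 0:
        raise ValueError("unit ratio must be positive")
    return hr**ratio, ci_low**ratio, ci_high**ratio


def rescale_effect(
    fit: SurvivalFit,
    term: str,
    to_unit: float,
    from_unit: float = 1.0,
) -> dict[str, float]:
    """HR/OR and CI for ``term`` per ``to_unit`` predictor units.

    ``from_unit`` is the increment the fitted coefficient refers to
    (1 unit unless the predictor was pre-scaled).  To report per SD, pass
    the sample SD of the predictor as ``to_unit``.
    """
    if term not in fit.summary.index:
        raise KeyError(f"term {term!r} not in fit")
    ratio = to_unit / from_unit
    hr, lo, hi = fit.hazard_ratio(term)
    hr2, lo2, hi2 = rescale_hr(hr, lo, hi, ratio)
    return {"hr": hr2, "ci_low": lo2, "ci_high": hi2, "ratio": ratio}
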