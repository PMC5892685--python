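"""Deficit-accumulation frailty index (FI).

The FI is the proportion of age-related health deficits present out of the
deficits considered (34 by default in this package's simulations).
Candidate deficits are screened by prevalence and age-trend rules before
the index is computed; missing deficit values are handled by multiple
imputation with chained per-deficit logistic models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationSet", "screen_deficits", "frailty_index", "impute_deficits"]


@dataclass
class ImputationSet:
    """A set of m completed deficit panels from multiple imputation."""

    panels: list[pd.DataFrame]
    seed: int

    @property
    def m(self) -> int:
        return len(self.panels)

    def frailty_indices(self) -> pd.DataFrame:
        """FI per subject for each completed panel (columns imp_1..imp_m)."""
        return pd.DataFrame(
            {f"imp_{i + 1}": frailty_index(p) for i, p in enumerate(self.panels)}
        )


def screen_deficits(
    panel: pd.DataFrame,
    ages: pd.Series,
    min_prevalence: float = 0.01,
    max_young_prevalence: float = 0.50,
    young_age: tuple[float, float] = (50.0, 60.0),
    trend_alpha: float = 0.05,
    keep: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen candidate deficits for FI eligibility.

    A deficit is retained when its overall prevalence exceeds
    ``min_prevalence`` (default 1%), its prevalence among subjects aged
    50-60 years does not exceed ``max_young_prevalence`` (default 50%,
    the "early saturation" rule), and it accumulates with age (positive
    Spearman correlation with age at ``trend_alpha``).  Deficits named in
    ``keep`` bypass screening (a stand-in for the health-status relevance
    judgement, which cannot be made from the panel alone).

    Returns the eligible panel and an exclusion report
    (deficit, rule, statistic).
    """
    ages = ages.reindex(panel.index)
    young = ages.between(*young_age)
    if not young.any():
        raise ValueError("no subjects in the 50-60 year window; cannot screen")

    keep = set(keep or [])
    records = []
    eligible = []
    for name in panel.columns:
        if name in keep:
            eligible.append(name)
            continue
        col = panel[name]
        prev = col.mean(skipna=True)
        if not prev > min_prevalence:
            records.append((name, "prevalence <= 1%", prev))
            continue
        prev_young = col[young].mean(skipna=True)
        if prev_young > max_young_prevalence:
            records.append((name, "early saturation", prev_young))
            continue
        obs = col.notna() & ages.notna()
        rho, p = stats.spearmanr(col[obs], ages[obs])
        if not (rho > 0 and p < trend_alpha):
            records.append((name, "no age trend", rho))
            continue
        eligible.append(name)

    report = pd.DataFrame(records, columns=["deficit", "rule", "statistic"])
    return panel[eligible], report


def frailty_index(panel: pd.DataFrame, denominator: str = "full") -> pd.Series:
    """FI = deficits present / deficits considered, per subject.

    The default path requires a completed (fully observed) panel; use
    ``denominator="observed"`` to divide by the number of observed deficits
    instead, in which case subjects with zero observed deficits get NaN
    with a warning.
    """
    if panel.shape[1] == 0:
        raise ValueError("deficit panel has no columns")
    vals = panel.to_numpy(dtype=float)
    if denominator == "full":
        if np.isnan(vals).any():
            raise ValueError(
                "panel contains missing values; impute first or use "
                "denominator='observed'"
            )
        fi = vals.mean(axis=1)
    elif denominator == "observed":
        n_obs = (~np.isnan(vals)).sum(axis=1)
        if (n_obs == 0).any():
            warnings.warn("subjects with zero observed deficits receive missing FI")
        with np.errstate(invalid="ignore"):
            fi = np.nansum(vals, axis=1) / np.where(n_obs == 0, np.nan, n_obs)
    else:
        raise ValueError("denominator must be 'full' or 'observed'")
    return pd.Series(fi, index=panel.index, name="fi")


def impute_deficits(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_sweeps: int = 3,
) -> ImputationSet:
    """Multiple imputation of missing deficit values (chained equations).

    Each deficit with missing values is modelled by logistic regression on
    the covariates (age and sex at minimum) and all other deficits at their
    current filled values; missing entries are replaced by Bernoulli draws
    from the fitted probabilities.  ``n_sweeps`` full passes are made per
    imputation after a marginal-prevalence initialization.  Deterministic
    given ``seed``.
    """
    if m < 2:
        raise ValueError("m >= 2 imputations required")
    covariates = covariates.reindex(panel.index)
    all_missing = panel.columns[panel.isna().all()]
    if len(all_missing):
        raise ValueError("deficits with all values missing: " + ", ".join(all_missing))

    mask = panel.isna()
    if not mask.to_numpy().any():
        return ImputationSet([panel.copy() for _ in range(m)], seed)

    rng = np.random.default_rng(seed)
    X_cov = covariates.to_numpy(dtype=float)
    panels = []
    incomplete = [c for c in panel.columns if mask[c].any()]
    for _ in range(m):
        filled = panel.copy()
        # initialize from observed marginal prevalence
        for c in incomplete:
            p0 = panel[c].mean(skipna=True)
            idx = mask[c]
            filled.loc[idx, c] = (rng.random(idx.sum()) < p0).astype(float)
        for _sweep in range(n_sweeps):
            for c in incomplete:
                others = filled.drop(columns=c).to_numpy(dtype=float)
                X = np.column_stack([X_cov, others])
                obs = ~mask[c].to_numpy()
                y_obs = panel[c].to_numpy(dtype=float)[obs]
                if y_obs.min() == y_obs.max():
                    # degenerate observed outcome: keep marginal draws
                    continue
                clf = LogisticRegression(max_iter=500, C=1.0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X[obs], y_obs)
                p_mis = clf.predict_proba(X[~obs])[:, 1]
                filled.loc[mask[c], c] = (rng.random(len(p_mis)) < p_mis).astype(float)
        panels.append(filled)
    return ImputationSet(panels, seed)
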