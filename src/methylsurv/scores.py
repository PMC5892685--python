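"""Methylation-based mortality risk scores and epigenetic age acceleration.

Two forms of the blood-methylation mortality risk score are computed from a
beta matrix (CpG rows x sample columns, values in [0, 1]):

* ``mrscore`` — a count in 0..10 of CpGs with "aberrant" methylation, where
  aberrance means membership in the extreme quartile in the direction
  associated with mortality (lowest quartile for the nine hypomethylated
  CpGs, highest quartile for the single hypermethylated CpG, cg08362785).
* ``cont_mrscore`` — a continuous weighted sum of the ten beta values with
  fixed published LASSO-derived weights.

Epigenetic age acceleration (AA) is the residual of DNA-methylation age
regressed on chronological age by ordinary least squares within the
analysis sample, so AA is uncorrelated with age by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "MRSCORE_WEIGHTS",
    "weight_table",
    "filter_probes",
    "cont_mrscore",
    "derive_thresholds",
    "mrscore",
    "categorize_mrscore",
    "age_acceleration",
    "zscore",
    "build_score_panel",
]

#: Published weights of the 10-CpG continuous mortality risk score
#: (per unit methylation beta).  cg08362785 is the unique hypermethylated
#: marker; all others are hypomethylated (lower methylation = higher risk).
MRSCORE_WEIGHTS: dict[str, float] = {
    "cg01612140": -0.38253,
    "cg05575921": -0.92224,
    "cg06126421": -1.70129,
    "cg08362785": 2.71749,
    "cg10321156": -0.02073,
    "cg14975410": -0.04156,
    "cg19572487": -0.28069,
    "cg23665802": -0.89440,
    "cg24704287": -2.98637,
    "cg25983901": -1.80325,
}

MRSCORE_CPGS: tuple[str, ...] = tuple(MRSCORE_WEIGHTS)


def weight_table(weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Return the score weight table (cpg_id index; weight, direction).

    Direction is ``hyper`` for positive weights (aberrance = high
    methylation) and ``hypo`` for negative weights.
    """
    w = MRSCORE_WEIGHTS if weights is None else dict(weights)
    tab = pd.DataFrame(
        {
            "weight": pd.Series(w, dtype=float),
            "direction": ["hyper" if v > 0 else "hypo" for v in w.values()],
        }
    )
    tab.index.name = "cpg_id"
    return tab


def filter_probes(
    betas: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    chromosome_map: pd.Series | None = None,
    p_cut: float = 0.01,
    miss_cut: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply array-QC probe filters to a beta matrix.

    Probes are excluded when they target the X or Y chromosome, or when
    their fraction of missing values exceeds ``miss_cut`` (default 10%).
    Values whose detection p-value exceeds ``p_cut`` (default 0.01) are set
    missing before the missingness test, so unreliably detected probes fail
    through that route and are reported with reason ``"detection"``.

    Returns the filtered matrix (detection failures masked to NaN) and an
    exclusion report with columns ``cpg_id``, ``reason``, ``statistic``.
    """
    miss_raw = betas.isna().mean(axis=1)
    masked = betas.copy()
    if detection_p is not None:
        detection_p = detection_p.reindex(index=betas.index, columns=betas.columns)
        masked = masked.mask(detection_p > p_cut)
    miss_after = masked.isna().mean(axis=1)

    if chromosome_map is not None:
        missing_ann = betas.index.difference(chromosome_map.index)
        if len(missing_ann):
            raise ValueError(
                "no chromosome annotation for probes: " + ", ".join(missing_ann[:10])
            )

    records = []
    keep = []
    for cpg in betas.index:
        if chromosome_map is not None and str(chromosome_map.loc[cpg]).removeprefix("chr") in ("X", "Y"):
            records.append((cpg, "sex chromosome", np.nan))
        elif miss_raw.loc[cpg] > miss_cut:
            records.append((cpg, "missingness", miss_raw.loc[cpg]))
        elif miss_after.loc[cpg] > miss_cut:
            records.append((cpg, "detection", miss_after.loc[cpg]))
        else:
            keep.append(cpg)

    report = pd.DataFrame(records, columns=["cpg_id", "reason", "statistic"])
    return masked.loc[keep], report


def _score_betas(betas: pd.DataFrame, cpgs) -> pd.DataFrame:
    missing = [c for c in cpgs if c not in betas.index]
    if missing:
        raise KeyError("score CpGs absent from beta matrix: " + ", ".join(missing))
    return betas.loc[list(cpgs)]


def cont_mrscore(betas: pd.DataFrame, weights: pd.DataFrame | None = None) -> pd.Series:
    """Continuous mortality risk score: weighted sum of 10 CpG betas.

    Subjects with any missing score CpG receive NaN (flagged, not dropped).
    """
    wt = weight_table() if weights is None else weights
    sub = _score_betas(betas, wt.index)
    score = sub.mul(wt["weight"], axis=0).sum(axis=0, min_count=len(wt))
    score.name = "cont_mrscore"
    return score


def derive_thresholds(
    betas: pd.DataFrame, weights: pd.DataFrame | None = None
) -> pd.DataFrame:
    """In-sample aberrance cutoffs for the count score.

    The cutoff is the first quartile of the sample betas for hypomethylated
    CpGs and the third quartile for the hypermethylated CpG, with linear
    interpolation between order statistics (the numpy default convention).
    """
    wt = weight_table() if weights is None else weights
    sub = _score_betas(betas, wt.index)
    if sub.shape[1] < 4:
        raise ValueError("at least 4 subjects required to derive quartiles")
    rows = []
    for cpg, row in wt.iterrows():
        vals = sub.loc[cpg].dropna().to_numpy()
        q = 0.75 if row["direction"] == "hyper" else 0.25
        cutoff = float(np.quantile(vals, q))
        if np.ptp(vals) == 0:
            warnings.warn(f"degenerate (constant) beta distribution for {cpg}")
        rows.append((cpg, cutoff, row["direction"]))
    tab = pd.DataFrame(rows, columns=["cpg_id", "cutoff", "direction"]).set_index("cpg_id")
    return tab


def mrscore(betas: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Count-based score (0-10) plus its reporting category.

    A CpG is aberrant when beta <= cutoff (hypo) or beta >= cutoff (hyper);
    inclusive boundaries keep all-tied degenerate columns well defined.
    """
    sub = _score_betas(betas, thresholds.index)
    hypo = thresholds["direction"] == "hypo"
    aberrant = sub.le(thresholds["cutoff"], axis=0)
    aberrant.loc[~hypo] = sub.ge(thresholds["cutoff"], axis=0).loc[~hypo]
    any_missing = sub.isna().any(axis=0)
    score = aberrant.sum(axis=0).astype(float)
    score[any_missing] = np.nan
    out = pd.DataFrame({"mrscore": score})
    out["mrscore_category"] = out["mrscore"].map(categorize_mrscore)
    return out


def categorize_mrscore(score: float) -> str | float:
    """Reporting categories for the count score: 0, 1, 2-5, >5."""
    if pd.isna(score):
        return np.nan
    if score == 0:
        return "0"
    if score == 1:
        return "1"
    if score <= 5:
        return "2-5"
    return ">5"


def age_acceleration(dnam_age: pd.Series, age: pd.Series) -> pd.Series:
    """Age acceleration: OLS residuals of DNAm age on chronological age."""
    dnam_age, age = dnam_age.align(age, join="inner")
    if len(age) < 3:
        raise ValueError("at least 3 subjects required")
    x = age.to_numpy(float)
    y = dnam_age.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = pd.Series(y - (intercept + slope * x), index=age.index, name="age_acceleration")
    return resid


def zscore(x: pd.Series) -> pd.Series:
    """Standardize within the analysis sample (mean 0, SD 1, ddof=1)."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-standardize {x.name!r}: zero or undefined SD")
    return (x - x.mean()) / sd


def build_score_panel(
    cohort: pd.DataFrame,
    betas: pd.DataFrame,
    fi: pd.Series | None = None,
    weights: pd.DataFrame | None = None,
    thresholds: pd.DataFrame | None = None,
    age_col: str = "age",
    dnam_age_col: str = "dnam_age",
) -> pd.DataFrame:
    """Assemble the per-subject indicator panel used by all analyses.

    Computes cont.MRscore, the count score and its category (cutoffs derived
    in-sample unless a threshold table is supplied), age acceleration, and
    attaches the frailty index; z-standardized columns (suffix ``_z``) are
    computed within this sample, matching per-SD effect reporting.
    """
    panel = pd.DataFrame(index=cohort.index)
    panel["cont_mrscore"] = cont_mrscore(betas, weights).reindex(cohort.index)
    thr = derive_thresholds(betas, weights) if thresholds is None else thresholds
    ms = mrscore(betas, thr).reindex(cohort.index)
    panel["mrscore"] = ms["mrscore"]
    panel["mrscore_category"] = ms["mrscore_category"]
    panel["dnam_age"] = cohort[dnam_age_col]
    panel["age_acceleration"] = age_acceleration(cohort[dnam_age_col], cohort[age_col])
    if fi is not None:
        panel["fi"] = fi.reindex(cohort.index)
    for col in ("mrscore", "cont_mrscore", "age_acceleration", "fi"):
        if col in panel:
            panel[col + "_z"] = zscore(panel[col])
    return panel
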