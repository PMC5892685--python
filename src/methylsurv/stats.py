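"""Association-stage statistics.

Random-intercept linear models (methylation experiment batch as the random
effect), Rubin's-rules pooling over multiply imputed datasets,
Benjamini-Hochberg FDR control, DerSimonian-Laird random-effects
meta-analysis, and Spearman correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectEstimate",
    "PooledEffect",
    "fit_random_intercept_lm",
    "pool_rubin",
    "bh_adjust",
    "dersimonian_laird",
    "spearman_matrix",
]

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    """One model coefficient with Wald 95% CI."""

    term: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class PooledEffect:
    """DerSimonian-Laird pooled effect across k studies."""

    term: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    q_statistic: float
    k: int


def fit_random_intercept_lm(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    groups: pd.Series,
) -> tuple[dict[str, EffectEstimate], dict[str, float]]:
    """Linear model with a random intercept per group, fitted by REML.

    Returns fixed-effect estimates per predictor (Wald CIs) and the
    variance components ``{"group_var", "resid_var"}``.  With a single
    group there is no information on the between-group variance, so the
    fit falls back to OLS with a warning.
    """
    df = pd.concat([outcome.rename("__y__"), predictors], axis=1).dropna()
    groups = groups.reindex(df.index)
    y = df["__y__"]
    X = sm.add_constant(df.drop(columns="__y__"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"singular design matrix; terms: {list(X.columns)}")
    n = len(df)

    if groups.nunique() <= 1:
        warnings.warn("single group: falling back to ordinary least squares")
        res = sm.OLS(y, X).fit()
        comps = {"group_var": 0.0, "resid_var": float(res.scale)}
    else:
        model = sm.MixedLM(y, X, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                # lbfgs can step through a singular region on small groups
                res = model.fit(reml=True, method="powell")
        comps = {
            "group_var": float(res.cov_re.iloc[0, 0]),
            "resid_var": float(res.scale),
        }

    effects = {}
    for term in X.columns:
        if term == "const":
            continue
        b = float(res.params[term])
        se = float(res.bse[term])
        effects[term] = EffectEstimate(
            term=term,
            coefficient=b,
            se=se,
            ci_low=b - _Z95 * se,
            ci_high=b + _Z95 * se,
            p_value=float(res.pvalues[term]),
            n=n,
        )
    return effects, comps


def pool_rubin(estimates: list[EffectEstimate]) -> EffectEstimate:
    """Combine estimates across m imputed datasets by Rubin's rules.

    Pooled coefficient is the mean; total variance is W + (1 + 1/m) B with
    W the mean within-imputation variance and B the between-imputation
    variance.  The CI and p-value use Rubin's t reference distribution
    with df = (m - 1) (1 + W / ((1 + 1/m) B))^2 (normal when B = 0).
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    terms = {e.term for e in estimates}
    if len(terms) != 1:
        raise ValueError(f"mismatched terms: {sorted(terms)}")
    q = np.array([e.coefficient for e in estimates])
    w = np.array([e.variance for e in estimates])
    qbar = q.mean()
    W = w.mean()
    B = q.var(ddof=1)
    total = W + (1 + 1 / m) * B
    se = np.sqrt(total)
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        tcrit = sps.t.ppf(0.975, df)
        p = 2 * sps.t.sf(abs(qbar / se), df)
    else:
        tcrit = _Z95
        p = 2 * sps.norm.sf(abs(qbar / se)) if se > 0 else (0.0 if qbar else 1.0)
    return EffectEstimate(
        term=estimates[0].term,
        coefficient=float(qbar),
        se=float(se),
        ci_low=float(qbar - tcrit * se),
        ci_high=float(qbar + tcrit * se),
        p_value=float(p),
        n=max(e.n for e in estimates),
    )


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    Returns (adjusted, reject) with discoveries flagged at adjusted <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj, adj <= q


def dersimonian_laird(estimates: list[EffectEstimate]) -> PooledEffect:
    """Random-effects meta-analysis (DerSimonian-Laird moments estimator).

    tau^2 = max(0, (Q - (k-1)) / C) with C = sum(w) - sum(w^2)/sum(w) from
    the fixed-effect inverse-variance weights w = 1/v_i; the pooled
    estimate uses weights 1/(v_i + tau^2) with a Wald 95% CI.
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("meta-analysis requires at least 2 estimates")
    terms = {e.term for e in estimates}
    if len(terms) != 1:
        raise ValueError(f"mismatched terms: {sorted(terms)}")
    y = np.array([e.coefficient for e in estimates])
    v = np.array([e.variance for e in estimates])
    if np.any(v <= 0):
        raise ValueError("all variances must be positive")
    w = 1 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    w_re = 1 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(np.sqrt(1 / np.sum(w_re)))
    return PooledEffect(
        term=estimates[0].term,
        coefficient=mu,
        se=se,
        ci_low=mu - _Z95 * se,
        ci_high=mu + _Z95 * se,
        p_value=float(2 * sps.norm.sf(abs(mu / se))),
        tau2=float(tau2),
        q_statistic=Q,
        k=k,
    )


def spearman_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix, diagonal 1.

    Constant columns yield NaN entries (undefined rank correlation) and a
    warning naming them.
    """
    if len(columns) < 3:
        raise ValueError("at least 3 subjects required")
    constant = [c for c in columns if columns[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn("constant columns have undefined correlations: " + ", ".join(constant))
    corr = columns.corr(method="spearman")
    for c in columns.columns:
        if c not in constant:
            corr.loc[c, c] = 1.0
    return corr
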