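"""Predictive-accuracy measures for survival indicators.

Harrell's concordance index with an asymptotic normal CI, inverse
probability of censoring weighted (IPCW) Brier prediction-error curves,
cumulative/dynamic time-dependent AUC under censoring, and the plain
rank-based AUC (C-index) for binary outcomes.

Censoring weights come from the Kaplan-Meier estimate G of the censoring
survival function: a subject with an event at T <= t is weighted 1/G(T-),
a subject still under observation past t is weighted 1/G(t), and a subject
censored before t contributes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter

__all__ = [
    "ConcordanceResult",
    "AccuracyReport",
    "harrell_c",
    "binary_auc",
    "brier_curve",
    "time_dependent_auc",
    "censoring_survival",
    "plot_accuracy_curves",
]

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int


@dataclass
class AccuracyReport:
    """Accuracy metrics for one predictor set on one sample."""

    label: str
    harrell: ConcordanceResult | None = None
    binary_auc: float | None = None
    time_grid: np.ndarray | None = None
    brier: pd.Series | None = None
    auc_t: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per grid time (long form) for TSV output."""
        if self.time_grid is None:
            return pd.DataFrame(
                {
                    "label": [self.label],
                    "time": [np.nan],
                    "harrell_c": [self.harrell.c if self.harrell else np.nan],
                    "binary_auc": [self.binary_auc],
                }
            )
        out = pd.DataFrame({"label": self.label, "time": self.time_grid})
        if self.brier is not None:
            out["brier"] = self.brier.reindex(self.time_grid).to_numpy()
        if self.auc_t is not None:
            out["auc_t"] = self.auc_t.reindex(self.time_grid).to_numpy()
        if self.harrell is not None:
            out["harrell_c"] = self.harrell.c
        return out


def _pair_counts(time, event, risk):
    """Vectorized comparable-pair statistics for Harrell's C.

    A pair is comparable when the member with the strictly earlier
    observed time had an event.  Returns total comparable pairs N, the
    concordance sum S (ties in risk count 0.5), and per-subject
    (n_i, s_i) for the asymptotic variance.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    r = np.asarray(risk, float)
    n = len(t)
    n_i = np.zeros(n)
    s_i = np.zeros(n)
    block = 512
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        ti, ei, ri = t[sl, None], e[sl, None], r[sl, None]
        earlier_i = (ti < t[None, :]) & (ei == 1)
        earlier_j = (t[None, :] < ti) & (e[None, :] == 1)
        comp = earlier_i | earlier_j
        # u = 1 when the earlier subject has the higher risk, 0.5 on ties
        hi_i = ri > r[None, :]
        ties = ri == r[None, :]
        u = np.where(earlier_i, np.where(hi_i, 1.0, 0.0), np.where(hi_i, 0.0, 1.0))
        u = np.where(ties, 0.5, u)
        u = np.where(comp, u, 0.0)
        n_i[sl] += comp.sum(axis=1)
        s_i[sl] += u.sum(axis=1)
    N = n_i.sum() / 2  # each pair counted from both ends
    S = s_i.sum() / 2
    return N, S, n_i, s_i


def harrell_c(time, event, risk, alpha: float = 0.05) -> ConcordanceResult:
    """Harrell's concordance index with an asymptotic normal CI.

    C = (concordant + 0.5 * tied-risk) / comparable pairs.  The standard
    error is a Noether-type estimate from per-subject sums of the pair
    indicators (a U-statistic / infinitesimal-jackknife form).
    """
    N, S, n_i, s_i = _pair_counts(time, event, risk)
    if N == 0:
        raise ValueError("no comparable pairs")
    c = S / N
    # each pair appears in two subject sums -> factor 2 in the influence;
    # Var(C) ~ sum_i (s_i - c n_i)^2 / N^2
    var = float(np.sum((s_i - c * n_i) ** 2)) / (N**2)
    se = np.sqrt(var)
    z = sps.norm.ppf(1 - alpha / 2)
    return ConcordanceResult(
        c=float(c),
        se=float(se),
        ci_low=float(max(0.0, c - z * se)),
        ci_high=float(min(1.0, c + z * se)),
        n_pairs=int(round(N)),
    )


def binary_auc(outcome, score) -> float:
    """Rank-based AUC (ties count half); C-index of a logistic model."""
    y = np.asarray(outcome, int)
    s = np.asarray(score, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(auc)


def censoring_survival(time, event):
    """Kaplan-Meier estimate of the censoring survival function G.

    Returns ``(G, G_minus)`` callables evaluating G(t) (right-continuous)
    and the left limit G(t-) on arrays.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), event_observed=1 - np.asarray(event, int))
    sf = kmf.survival_function_.iloc[:, 0]
    knots = sf.index.to_numpy(float)
    vals = sf.to_numpy(float)

    def G(t):
        idx = np.searchsorted(knots, np.asarray(t, float), side="right") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])

    def G_minus(t):
        idx = np.searchsorted(knots, np.asarray(t, float), side="left") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])

    return G, G_minus


def brier_curve(
    time_grid,
    time,
    event,
    surv_prob: pd.DataFrame,
    censor_time=None,
    censor_event=None,
) -> pd.Series:
    """IPCW Brier prediction-error curve over a time grid.

    ``surv_prob`` holds predicted survival probabilities S(t|x) with the
    grid times as rows and subjects as columns (the layout of lifelines'
    ``predict_survival_function``).  Censoring weights are Kaplan-Meier
    based; grid points where G(t) = 0 are dropped with a warning.  With no
    censoring the weights collapse to 1 and the result is the plain mean
    squared error between 1{T > t} and S(t|x).
    """
    grid = np.asarray(time_grid, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    G, G_minus = censoring_survival(
        t if censor_time is None else np.asarray(censor_time, float),
        e if censor_event is None else np.asarray(censor_event, int),
    )
    gm_t = G_minus(t)  # G(T_i-)
    usable = grid[G(grid) > 0]
    if len(usable) < len(grid):
        warnings.warn("time grid truncated where censoring survival reaches 0")
    out = {}
    for tt in usable:
        S = surv_prob.loc[tt].to_numpy(float)
        died = (t <= tt) & (e == 1)
        alive = t > tt
        w = np.zeros_like(t)
        w[died] = 1.0 / gm_t[died]
        w[alive] = 1.0 / float(G(tt))
        resid = np.where(died, (0.0 - S) ** 2, (1.0 - S) ** 2)
        out[tt] = float(np.sum(w * resid) / len(t))
    return pd.Series(out, name="brier")


def time_dependent_auc(time_grid, time, event, risk) -> pd.Series:
    """Cumulative-cases / dynamic-controls AUC(t) with IPCW.

    At each grid time t, cases are subjects with an observed event by t
    and controls those still at risk beyond t; cases are weighted by
    1/G(T-).  With no censoring this equals the binary AUC of the
    event-by-t indicator.
    """
    grid = np.asarray(time_grid, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    r = np.asarray(risk, float)
    _, G_minus = censoring_survival(t, e)
    gm = G_minus(t)
    out = {}
    for tt in grid:
        case = (t <= tt) & (e == 1)
        ctrl = t > tt
        if not case.any() or not ctrl.any():
            raise ValueError(f"degenerate case/control split at t={tt}")
        w = 1.0 / gm[case]
        rc, rk = r[case], r[ctrl]
        # weighted Mann-Whitney: sum over cases of w_i * P(case risk > ctrl)
        gt = (rc[:, None] > rk[None, :]).sum(axis=1)
        eq = (rc[:, None] == rk[None, :]).sum(axis=1)
        num = float(np.sum(w * (gt + 0.5 * eq)))
        den = float(np.sum(w) * len(rk))
        out[tt] = num / den
    return pd.Series(out, name="auc_t")


def plot_accuracy_curves(curves: pd.DataFrame, metric: str = "brier", path=None):
    """Line chart of Brier(t) or AUC(t) per predictor set.

    ``curves`` is the long-form table produced by the pipeline (columns
    label, time, brier, auc_t).  Writes SVG/PNG when ``path`` is given,
    otherwise returns the matplotlib axes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, grp in curves.groupby("label"):
        ax.plot(grp["time"], grp[metric], marker="o", ms=3, label=label)
    ax.set_xlabel("years since baseline")
    ax.set_ylabel("prediction error (Brier)" if metric == "brier" else "AUC(t)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return ax
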