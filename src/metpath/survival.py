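"""Survival-analysis primitives shared by the prognosis models.

Implements the Cox partial log-likelihood (Breslow handling of ties),
its gradient with respect to the per-sample log hazard ratio, Harrell's
concordance index, the two-group log-rank test, risk-group
dichotomization of a prognosis index (PI), and Kaplan-Meier step
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import SurvivalData

__all__ = [
    "cox_partial_loglik",
    "cox_partial_loglik_grad",
    "c_index",
    "logrank_test",
    "dichotomize",
    "km_table",
]


def _risk_matrix(time: np.ndarray) -> np.ndarray:
    """R[i, j] = 1 when sample j is at risk at sample i's time (t_j >= t_i)."""
    return (time[None, :] >= time[:, None]).astype(float)


def cox_partial_loglik(theta: np.ndarray, surv: SurvivalData) -> float:
    """Cox partial log-likelihood of a log-hazard-ratio vector.

    pl(theta) = sum over event samples i of
    theta_i - log sum_{j : t_j >= t_i} exp(theta_j).
    Tied event times share the same risk set (Breslow).
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) != len(surv):
        raise ValueError("theta must be aligned with the survival data")
    if surv.n_events == 0:
        raise ValueError("no observed events: partial likelihood undefined")
    events = surv.event == 1
    # log-sum-exp over each event's risk set, stabilized
    c = theta.max()
    e = np.exp(theta - c)
    risk_sums = _risk_matrix(surv.time) @ e
    log_risk = np.log(risk_sums) + c
    return float(np.sum(theta[events] - log_risk[events]))


def cox_partial_loglik_grad(theta: np.ndarray, surv: SurvivalData) -> np.ndarray:
    """Gradient of :func:`cox_partial_loglik` with respect to theta."""
    theta = np.asarray(theta, dtype=float)
    events = (surv.event == 1).astype(float)
    c = theta.max()
    e = np.exp(theta - c)
    R = _risk_matrix(surv.time)
    risk_sums = R @ e
    # d/dtheta_j: delta_j - exp(theta_j) * sum over events i with t_j >= t_i of 1/risk_sum_i
    weights = events / risk_sums
    return events - e * (R.T @ weights)


def c_index(pi: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's concordance index of a prognosis index.

    Over comparable pairs (the earlier time is an observed event), the
    fraction where the earlier-failing sample has the larger PI; ties
    in PI count 0.5.  A value of 1 is perfect ranking, 0.5 is random.
    """
    pi = np.asarray(pi, dtype=float)
    t, d = surv.time, surv.event
    # pair (i, j) comparable when t_i < t_j and event i observed
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs: C-index undefined")
    diff = pi[:, None] - pi[None, :]
    concordant = float(np.sum(comparable & (diff > 0)))
    tied = float(np.sum(comparable & (diff == 0)))
    return (concordant + 0.5 * tied) / n_pairs


def logrank_test(groups: np.ndarray, surv: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` holds 'high'/'low' labels (or any two labels); samples
    labeled 'excluded' are dropped.  Returns ``(statistic, p_value)``
    with the statistic referred to chi-square with 1 df.
    """
    groups = np.asarray(groups, dtype=object)
    keep = groups != "excluded"
    groups, t, d = groups[keep], surv.time[keep], surv.event[keep]
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {list(labels)}")
    g1 = groups == labels[0]
    if t[g1].sum() == 0 or t[~g1].sum() == 0:
        raise ValueError("a group has zero at-risk time")
    obs, exp, var = 0.0, 0.0, 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        dj = ((t == tt) & (d == 1)).sum()
        d1 = ((t == tt) & (d == 1) & g1).sum()
        obs += d1
        exp += dj * n1 / n
        if n > 1:
            var += dj * (n1 / n) * (1 - n1 / n) * (n - dj) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = (obs - exp) ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def dichotomize(
    pi: np.ndarray, surv: SurvivalData, method: str = "median"
) -> np.ndarray:
    """Split samples into high/low risk groups by their prognosis index.

    Methods
    -------
    median
        PI <= median -> 'low', else 'high' (default).
    event_ratio
        The k largest PIs are 'high', where k is the observed event count.
    quartile
        PI below the first quartile -> 'low', above the third -> 'high',
        the middle half 'excluded' (type-7 linear-interpolation quantiles).
    q1_threshold
        PI <= first quartile -> 'low', else 'high' (single-threshold
        variant of the quartile split).
    """
    pi = np.asarray(pi, dtype=float)
    n = len(pi)
    if np.all(pi == pi[0]):
        raise ValueError("all prognosis indices identical: no split possible")
    out = np.empty(n, dtype=object)
    if method == "median":
        med = np.median(pi)
        out[:] = np.where(pi <= med, "low", "high")
    elif method == "event_ratio":
        k = surv.n_events
        order = np.argsort(-pi, kind="stable")
        out[:] = "low"
        out[order[:k]] = "high"
    elif method == "quartile":
        if n < 4:
            raise ValueError("quartile dichotomization needs n >= 4")
        q1, q3 = np.quantile(pi, [0.25, 0.75])  # type-7 (linear) rule
        out[:] = "excluded"
        out[pi < q1] = "low"
        out[pi > q3] = "high"
    elif method == "q1_threshold":
        q1 = np.quantile(pi, 0.25)
        out[:] = np.where(pi <= q1, "low", "high")
    else:
        raise ValueError(f"unknown dichotomization method {method!r}")
    return out


def km_table(surv: SurvivalData, groups: np.ndarray | None = None) -> pd.DataFrame:
    """Kaplan-Meier step tables: (group, time, survival, at_risk) rows."""
    if groups is None:
        groups = np.array(["all"] * len(surv), dtype=object)
    groups = np.asarray(groups, dtype=object)
    frames = []
    for g in np.unique(groups[groups != "excluded"]):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[sel], surv.event[sel])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
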