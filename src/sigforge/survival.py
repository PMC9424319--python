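"""Survival statistics: Kaplan-Meier curves, log-rank tests, Cox PH models.

Every downstream stage (single-gene screening, SGR refinement, risk-group
maximization, subgroup analysis) funnels through the three operations here.
Kaplan-Meier and Cox fitting are backed by lifelines; the k-sample log-rank
statistic is computed directly with numpy because the cutoff-scanning and
greedy-elimination loops evaluate it many thousands of times per analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "km_fit",
    "logrank_test",
    "cox_fit",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median_survival: float | None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, float)
        self.survival = np.asarray(self.survival, float)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxResult:
    """Cox proportional-hazards fit: log-hazard coefficients and Wald inference."""

    names: list[str]
    beta: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "converged": self.converged,
            "covariates": [
                {
                    "name": n,
                    "beta": float(b),
                    "hr": float(h),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "wald_p": float(p),
                }
                for n, b, h, lo, hi, p in zip(
                    self.names, self.beta, self.hr, self.ci_low, self.ci_high, self.wald_p
                )
            ],
        }


def _check_time_event(time, event):
    time = np.asarray(time, float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValidationError("empty survival input")
    if time.shape != event.shape:
        raise ValidationError("time and event must have equal length")
    if (time < 0).any():
        raise ValidationError("negative follow-up time")
    if not np.isin(event, [0, 1]).all():
        raise ValidationError("event indicator must be 0/1")
    return time, event.astype(int)


def km_fit(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Median survival is the smallest observed event time at which the curve
    reaches 0.5 or below; ``None`` when the curve never gets there.
    """
    time, event = _check_time_event(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    ev_times = table.index.to_numpy(float)[mask]
    at_risk = table["at_risk"].to_numpy(float)[mask]
    d = table["observed"].to_numpy(float)[mask]
    surv = (
        kmf.survival_function_["KM_estimate"].reindex(ev_times).to_numpy(float)
        if ev_times.size
        else np.array([])
    )
    crossing = np.flatnonzero(surv <= 0.5)
    median = float(ev_times[crossing[0]]) if crossing.size else None
    return SurvivalCurve(ev_times, surv, at_risk, d, median)


def logrank_test(time, event, group) -> LogRankResult:
    """k-sample log-rank test.

    At each distinct event time the observed events per group are compared
    with their expectation under the hypergeometric model given the risk
    sets; the quadratic form of (O - E) against its covariance yields a
    chi-square statistic with ``k - 1`` degrees of freedom.
    """
    time, event = _check_time_event(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    k = levels.size
    if k < 2:
        raise ValidationError(f"log-rank needs >=2 groups, got {k}")
    if event.sum() == 0:
        raise ValidationError("no events observed; log-rank statistic undefined")

    ev_times = np.unique(time[event == 1])
    m = ev_times.size
    n_at_risk = np.empty((k, m))
    d_obs = np.empty((k, m))
    for i, lev in enumerate(levels):
        sel = group == lev
        if not sel.any():
            raise ValidationError(f"group {lev!r} is empty")
        t_i = np.sort(time[sel])
        n_at_risk[i] = t_i.size - np.searchsorted(t_i, ev_times, side="left")
        te = np.sort(time[sel & (event == 1)])
        d_obs[i] = np.searchsorted(te, ev_times, side="right") - np.searchsorted(
            te, ev_times, side="left"
        )
    n_tot = n_at_risk.sum(axis=0)
    d_tot = d_obs.sum(axis=0)
    p_frac = n_at_risk / n_tot  # k x m
    expected = d_tot * p_frac
    o_minus_e = (d_obs - expected).sum(axis=1)[: k - 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    pr = p_frac[: k - 1]  # (k-1) x m
    # V = sum_j c_j * (diag(p_j) - p_j p_j^T), restricted to first k-1 groups
    V = np.einsum("m,im,jm->ij", c, pr, pr) * -1.0
    V[np.diag_indices(k - 1)] += (c * pr).sum(axis=1)
    try:
        sol = np.linalg.solve(V, o_minus_e)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(V) @ o_minus_e
    statistic = float(max(o_minus_e @ sol, 0.0))
    p = float(stats.chi2.sf(statistic, k - 1))
    return LogRankResult(statistic=statistic, df=k - 1, p=p)


def cox_fit(covariates, time, event, names: list[str] | None = None) -> CoxResult:
    """Cox proportional-hazards regression (Efron tie handling, Wald CIs).

    ``covariates`` is an (n, p) matrix. Perfect separation / monotone
    likelihood is reported through ``converged=False`` rather than raising.
    """
    import pandas as pd

    time, event = _check_time_event(time, event)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if time.size != n:
        raise ValidationError("covariate rows must match number of subjects")
    if n <= p:
        raise ValidationError(f"need n > number of covariates ({n} <= {p})")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise DegenerateDataError(f"constant covariate(s): {bad}")

    df = pd.DataFrame(X, columns=names)
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    except ConvergenceError:
        nan = np.full(p, np.nan)
        return CoxResult(names, nan, nan, nan, nan, nan, converged=False)

    beta = cph.params_.to_numpy(float)
    ci = cph.confidence_intervals_.to_numpy(float)
    with np.errstate(over="ignore"):  # tiny risk sets can give +/-inf CI bounds
        hr, ci_low, ci_high = np.exp(beta), np.exp(ci[:, 0]), np.exp(ci[:, 1])
    return CoxResult(
        names=names,
        beta=beta,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=cph.summary["p"].to_numpy(float),
        converged=converged,
    )
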