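"""Kaplan-Meier, log-rank and Cox proportional-hazards analyses.

Times are in months. PFS events are progression or death, OS events death;
subjects without an event are censored at last follow-up. Estimation is
delegated to lifelines (product-limit estimator with Greenwood variance,
log-rank chi-square with 1 df, Efron tie handling for Cox partial
likelihood, Wald confidence intervals), wrapped behind small result types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KmCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "multivariable_screen",
    "one_year_status",
]


@dataclass
class KmCurve:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be non-increasing")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "greenwood_var": self.variance,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class CoxFit:
    summary: pd.DataFrame          # coef, HR, CI bounds, p per covariate
    tie_method: str = "efron"
    converged: bool = True
    penalizer: float = 0.0
    warnings_: list[str] = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def one_year_status(times, events, cutoff: float = 12.0) -> np.ndarray:
    """1-year progression status: event at or before the cutoff (months)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    return (events & (times <= cutoff)).astype(int)


def km_estimate(times, events) -> KmCurve:
    """Product-limit survival estimate with Greenwood variance and the
    (lifelines default) exponential log-log 95% CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # evaluate at the distinct event times (the steps of the estimator)
    grid = np.unique(times[events == 1])
    if grid.size == 0:
        grid = np.array([times.max()])
    surv = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_
    lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    # Greenwood: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    et = kmf.event_table
    d = et["observed"].to_numpy(dtype=float)
    n = et["at_risk"].to_numpy(dtype=float)
    tgrid = et.index.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n - d > 0, d / (n * (n - d)), 0.0)
    cum = np.cumsum(terms)
    var = np.array(
        [
            surv[i] ** 2 * (cum[tgrid <= t][-1] if np.any(tgrid <= t) else 0.0)
            for i, t in enumerate(grid)
        ]
    )
    at_risk = np.array([(times >= t).sum() for t in grid])
    return KmCurve(
        times=grid, survival=surv, variance=var,
        ci_lower=lo, ci_upper=hi, at_risk=at_risk,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.sum(events_a) + np.sum(events_b) == 0:
        warnings.warn("no events in either group: log-rank undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs).

    Monotone-likelihood problems (perfect separation in time) are caught
    and refit with a small ridge penalizer, reported on the result.
    """
    covariates = covariates or [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    df = data[covariates + [duration_col, event_col]]
    msgs: list[str] = []
    penalizer = 0.0
    cph = CoxPHFitter(penalizer=penalizer)
    diverged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        coefs = cph.summary["coef"].to_numpy()
        ses = cph.summary["se(coef)"].to_numpy()
        # monotone likelihood drives |coef| (and its SE) toward infinity
        # without necessarily tripping the optimizer
        diverged = not np.all(np.isfinite(coefs)) or np.any(
            np.abs(coefs) > 15
        ) or not np.all(np.isfinite(ses))
    except ConvergenceError:
        diverged = True
    if diverged:
        penalizer = 0.1
        msgs.append(
            "monotone likelihood or separation detected; refit with ridge "
            f"penalizer {penalizer}"
        )
        warnings.warn(msgs[-1], stacklevel=2)
        cph = CoxPHFitter(penalizer=penalizer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "hr_ci_lower": np.exp(s["coef lower 95%"]),
            "hr_ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxFit(summary=summary, tie_method=ties, converged=True,
                  penalizer=penalizer, warnings_=msgs)


def multivariable_screen(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: list[str],
    p_enter: float = 0.20,
) -> dict:
    """Univariable Cox fits, then a joint model with the p < p_enter subset.

    Returns ``{"univariable": DataFrame, "entered": [...], "multivariable":
    CoxFit | None}``.
    """
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    uni_rows = []
    for c in candidates:
        fit = cox_fit(data, duration_col, event_col, [c])
        row = fit.summary.loc[c].copy()
        row["covariate"] = c
        uni_rows.append(row)
    uni = pd.DataFrame(uni_rows).set_index("covariate")
    entered = [c for c in candidates if uni.loc[c, "p"] < p_enter]
    multi = (
        cox_fit(data, duration_col, event_col, entered) if entered else None
    )
    return {"univariable": uni, "entered": entered, "multivariable": multi}
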