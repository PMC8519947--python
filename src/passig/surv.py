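"""Survival stratification and tests: Kaplan-Meier, log-rank, Cox HR.

Samples are split into high/low strata at the mean of their logistic odds;
the strata are compared with the product-limit estimator, the two-sided
log-rank test, and a binary-covariate Cox proportional-hazards model (Efron
tie handling, via lifelines). The hazard ratio is reported low-vs-high: HR
above 1 means the low-odds stratum progresses or dies faster, the direction
expected when high signature scores mark responders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .datamodel import PassigError

__all__ = ["KMFit", "CoxResult", "LogRankResult", "stratify_by_mean_odds",
           "km_fit", "logrank_test", "cox_hr_binary"]


@dataclass
class KMFit:
    times: np.ndarray              # event/censor times where the curve changes
    survival: np.ndarray           # S(t) just after each time
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


@dataclass
class LogRankResult:
    chi_square: float
    pvalue: float


@dataclass
class CoxResult:
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    converged: bool


def stratify_by_mean_odds(odds: pd.Series) -> pd.Series:
    """Label samples 'high' when odds strictly exceed the mean, else 'low'."""
    if len(odds) < 2:
        raise ValueError("need at least 2 samples to stratify")
    mean = float(np.mean(odds))
    strata = pd.Series(np.where(odds > mean, "high", "low"), index=odds.index,
                       name="stratum")
    if (strata == "low").all():
        warnings.warn("all odds at or below the mean; every sample is 'low'",
                      stacklevel=2)
    return strata


def km_fit(times, events) -> KMFit:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    # drop the t=0 anchor row unless an event occurs at 0
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = np.array([int((t >= g).sum()) for g in grid])
    return KMFit(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sided log-rank comparison of two strata."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both strata must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise PassigError("log-rank test undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi_square=float(res.test_statistic),
                         pvalue=float(res.p_value))


def cox_hr_binary(times, events, group) -> CoxResult:
    """Cox proportional-hazards HR for a binary group indicator.

    ``group`` is 0/1 (or boolean); the coefficient is the log hazard of
    group 1 relative to group 0. Efron handling for tied event times.
    Monotone-likelihood failures return an infinite-HR sentinel with
    ``converged=False``.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": np.asarray(group, dtype=float),
    })
    if df["group"].nunique() != 2:
        raise ValueError("group indicator must take exactly two values")
    events_by_group = df.groupby("group")["event"].sum()
    if (events_by_group == 0).any():
        direction = 1.0 if events_by_group.get(1.0, 0) > 0 else -1.0
        return CoxResult(coef=direction * np.inf, hr=np.inf if direction > 0 else 0.0,
                         ci_low=0.0, ci_high=np.inf, pvalue=1.0, converged=False)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-12, "max_steps": 500})
    except ConvergenceError:
        return CoxResult(coef=np.inf, hr=np.inf, ci_low=0.0, ci_high=np.inf,
                         pvalue=1.0, converged=False)
    row = cph.summary.loc["group"]
    return CoxResult(
        coef=float(row["coef"]),
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        pvalue=float(row["p"]),
        converged=True,
    )
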