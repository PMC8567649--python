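"""Kaplan-Meier estimation, log-rank comparison and Cox PH fitting.

Time is follow-up in months; the event indicator is 1 for an observed
death/progression and 0 for censoring.  Estimation is delegated to
lifelines (product-limit KM, Mantel-Haenszel log-rank, Efron-tie Cox
partial likelihood); this module owns validation, the Greenwood variance
of the KM curve, and tidy result containers mirroring a forest-plot table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceError

from .errors import DegenerateInputError, FittingError, InputError, ValidationError


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray                 # distinct event times (ascending)
    survival: np.ndarray              # S(t) just after each event time
    at_risk: np.ndarray
    greenwood_se: np.ndarray
    median: float                     # NaN when S never reaches 0.5


@dataclass(frozen=True)
class LogrankResult:
    statistic: float                  # chi-square, df=1
    df: int
    p: float


@dataclass(frozen=True)
class CoxResult:
    summary: pd.DataFrame             # covariate, coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.set_index("covariate").loc[covariate, "hr"])


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if len(times) == 0:
        raise InputError("need at least one survival record")
    if not np.all(times > 0):
        raise ValidationError("survival times must be strictly positive")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("event indicator must be 0 (censored) or 1 (event)")
    return times, events.astype(int)


def km_fit(times, events) -> KMEstimate:
    """Product-limit survival estimate with Greenwood standard errors.

    The median is the first time at which S(t) <= 0.5, NaN when the curve
    never reaches 0.5 (e.g. all records censored).
    """
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    s_curve = kmf.survival_function_["KM_estimate"]
    surv = s_curve.loc[event_rows.index].to_numpy()
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_j<=t} d_j / (n_j (n_j - d_j))
    d = event_rows["observed"].to_numpy(dtype=float)
    n = event_rows["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = d / (n * (n - d))
    cum = np.cumsum(np.where(np.isfinite(increments), increments, 0.0))
    se = surv * np.sqrt(cum)
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMEstimate(times=event_rows.index.to_numpy(dtype=float),
                      survival=surv,
                      at_risk=n.astype(int),
                      greenwood_se=se,
                      median=median)


def km_curve_frame(est: KMEstimate) -> pd.DataFrame:
    """KM curve points as a plotting-ready frame."""
    return pd.DataFrame({"time": est.times, "survival": est.survival,
                         "at_risk": est.at_risk, "greenwood_se": est.greenwood_se})


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sample log-rank test (chi-square with 1 df)."""
    times_a, events_a = _validate(times_a, events_a)
    times_b, events_b = _validate(times_b, events_b)
    if events_a.sum() + events_b.sum() == 0:
        raise DegenerateInputError("log-rank test needs at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return LogrankResult(statistic=float(res.test_statistic), df=1, p=float(res.p_value))


def cox_fit(covariates: pd.DataFrame, times, events, ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit by maximum partial likelihood.

    ``covariates`` is patients x covariates (numeric; binary markers coded
    0/1).  Hazard ratios are exp(coef) with Wald 95% CIs.  Efron tie
    handling by default.
    """
    times, events = _validate(times, events)
    cov = pd.DataFrame(covariates).astype(float).reset_index(drop=True)
    if cov.shape[0] != len(times):
        raise InputError("covariate rows must match survival records")
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        raise InputError(f"constant covariate(s): {constant}")
    if events.sum() < cov.shape[1] + 1:
        raise DegenerateInputError(
            f"{int(events.sum())} events cannot support {cov.shape[1]} covariates")
    df = cov.copy()
    df["_time"] = times
    df["_event"] = events
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise FittingError(f"Cox fit failed to converge: {exc}") from exc
    s = fitter.summary
    summary = pd.DataFrame({
        "covariate": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": s["exp(coef)"].to_numpy(),
        "ci_low": s["exp(coef) lower 95%"].to_numpy(),
        "ci_high": s["exp(coef) upper 95%"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(summary=summary,
                     log_likelihood=float(fitter.log_likelihood_),
                     n=len(times), n_events=int(events.sum()))


def forest_table(result: CoxResult) -> pd.DataFrame:
    """Forest-plot table (covariate, HR, CI bounds, p)."""
    return result.summary[["covariate", "hr", "ci_low", "ci_high", "p"]].copy()
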