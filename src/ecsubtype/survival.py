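"""Survival analysis layer: Kaplan–Meier curves, log-rank tests, Cox models.

Thin, validated wrappers around :mod:`lifelines` (product-limit estimation
and the k-group log-rank test) and :mod:`statsmodels` (Cox partial-
likelihood fits with Efron or Breslow tie handling), returning small
result containers so the rest of the package never touches the fitting
libraries directly.

Times are in months throughout; the 10-year horizon is 120 months.
Kaplan–Meier confidence bands are Greenwood-based on the log(-log) scale,
which keeps them inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "DegenerateInputError",
    "km_estimate",
    "curve_summary",
    "logrank_test",
    "cox_ph",
    "TEN_YEARS_MONTHS",
]

TEN_YEARS_MONTHS = 120.0


class DegenerateInputError(ValueError):
    """Input admits no informative fit (constant covariate, single group, ...)."""


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    s_hat: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly ascending")
        if np.any(np.diff(self.s_hat) > 1e-12):
            raise ValueError("s_hat must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous; S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.s_hat[idx])


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class CoxResult:
    """Per-covariate table plus model-level metadata.

    ``table`` columns: log_hr, hr, ci95_low, ci95_high, p_value (index =
    covariate names).  HRs and their Wald CIs are exponentiated log-HRs.
    """

    table: pd.DataFrame
    n: int
    n_events: int
    converged: bool
    ties_method: str


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with 95% log(-log) bands."""
    times, events = _validate_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)

    table = kmf.event_table
    is_event = table["observed"] > 0
    evt = table[is_event]
    event_times = evt.index.to_numpy(dtype=float)
    s_hat = kmf.survival_function_.loc[event_times, "KM_estimate"].to_numpy()
    at_risk = evt["at_risk"].to_numpy(dtype=int)
    ci = kmf.confidence_interval_survival_function_
    ci_low = ci.iloc[:, 0].loc[event_times].to_numpy()
    ci_high = ci.iloc[:, 1].loc[event_times].to_numpy()
    return SurvivalCurve(
        event_times=event_times,
        s_hat=s_hat,
        at_risk=at_risk,
        ci_low=ci_low,
        ci_high=ci_high,
        n=int(times.size),
        n_events=int(events.sum()),
    )


def curve_summary(curve: SurvivalCurve, horizon_months: float = TEN_YEARS_MONTHS) -> dict:
    """Survival rate at a horizon and the median survival time.

    The rate is S at the last event time at or before the horizon (1.0
    when no event precedes it).  The median is the smallest event time at
    which S drops to 0.5 or below; None means "not reached".
    """
    if horizon_months < 0:
        raise ValueError("horizon must be >= 0")
    rate = curve.survival_at(horizon_months)
    below = np.nonzero(curve.s_hat <= 0.5)[0]
    median = float(curve.event_times[below[0]]) if below.size else None
    return {"rate_at_horizon": rate, "median_months": median}


def logrank_test(times, events, groups) -> LogRankResult:
    """k-group log-rank test; chi-square with k-1 degrees of freedom."""
    times, events = _validate_times_events(times, events)
    groups = np.asarray(groups)
    if groups.shape != times.shape:
        raise ValueError("groups must align with times")
    k = len(np.unique(groups))
    if k < 2:
        raise DegenerateInputError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    chi2 = float(res.test_statistic)
    return LogRankResult(chi2=max(chi2, 0.0), df=k - 1, p_value=float(res.p_value))


def _fit_partial_likelihood(
    X: pd.DataFrame, times: np.ndarray, events: np.ndarray, ties_method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximize the Cox partial likelihood, robustly.

    Efron ties go through lifelines' damped Newton iteration: with sparse
    events and strong effects an undamped quasi-Newton step can run off to
    huge coefficients, so progressively smaller step sizes are tried.
    Breslow ties use statsmodels PHReg (lifelines fits Efron only).
    Returns (log_hr, se, p_values), possibly non-finite on true failure.
    """
    nan = np.full(X.shape[1], np.nan)
    if ties_method == "breslow":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = PHReg(times, X.to_numpy(), status=events, ties="breslow").fit(disp=False)
            return (np.asarray(fit.params, float), np.asarray(fit.bse, float),
                    np.asarray(fit.pvalues, float))
        except Exception:
            return nan, nan, nan

    df = X.copy()
    df["__time"], df["__event"] = times, events
    for step_size in (None, 0.25, 0.1):
        options = {"step_size": step_size} if step_size is not None else {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="__time", event_col="__event",
                        fit_options=options)
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        params = cph.params_.reindex(X.columns).to_numpy(float)
        se = cph.standard_errors_.reindex(X.columns).to_numpy(float)
        pvals = cph.summary["p"].reindex(X.columns).to_numpy(float)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 50.0:
            return params, se, pvals
    return nan, nan, nan


def cox_ph(covariates, times, events, ties_method: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit via partial-likelihood maximization.

    ``covariates`` is a DataFrame (or 2-D array) of numeric columns; Wald
    95% CIs and p-values are reported per covariate.  Ties are handled by
    the Efron approximation by default; Breslow is available.
    Non-convergence is flagged on the result, not silently ignored.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    X = pd.DataFrame(covariates).apply(pd.to_numeric)
    times, events = _validate_times_events(times, events)
    if len(X) != times.size:
        raise ValueError("covariate rows must align with times")
    if times.size <= X.shape[1]:
        raise DegenerateInputError("need more subjects than covariates")
    stds = X.std(axis=0, ddof=0)
    constant = list(X.columns[stds.to_numpy() == 0])
    if constant:
        raise DegenerateInputError(f"constant covariate(s): {constant}")

    log_hr, se, pvals = _fit_partial_likelihood(X, times, events, ties_method)
    converged = bool(
        np.all(np.isfinite(log_hr)) and np.all(np.isfinite(se))
        and np.max(np.abs(log_hr)) < 50.0
    )
    if not converged:
        table = pd.DataFrame(
            np.nan,
            index=list(X.columns),
            columns=["log_hr", "hr", "ci95_low", "ci95_high", "p_value"],
        )
        return CoxResult(table=table, n=int(times.size), n_events=int(events.sum()),
                         converged=False, ties_method=ties_method)

    z = 1.959963984540054  # Phi^{-1}(0.975)
    with np.errstate(over="ignore"):  # an inf CI bound is reported as such
        table = pd.DataFrame(
            {
                "log_hr": log_hr,
                "hr": np.exp(log_hr),
                "ci95_low": np.exp(log_hr - z * se),
                "ci95_high": np.exp(log_hr + z * se),
                "p_value": pvals,
            },
            index=list(X.columns),
        )
    return CoxResult(
        table=table,
        n=int(times.size),
        n_events=int(events.sum()),
        converged=converged,
        ties_method=ties_method,
    )


def group_survival_report(
    times, events, groups, horizon_months: float = TEN_YEARS_MONTHS
) -> pd.DataFrame:
    """Per-group n, events, rate at the horizon and median survival."""
    times, events = _validate_times_events(times, events)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        curve = km_estimate(times[mask], events[mask])
        summ = curve_summary(curve, horizon_months)
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "events": int(events[mask].sum()),
                f"rate_at_{int(horizon_months)}m": summ["rate_at_horizon"],
                "median_months": summ["median_months"],
            }
        )
    return pd.DataFrame(rows)


def os_model_covariates(clinical: pd.DataFrame, labels: dict[str, str]) -> pd.DataFrame:
    """Covariate coding for the multivariate OS model.

    Age dichotomized at 55, stage binarized I-II vs III-IV ("later
    stage"), LVSI yes vs no, and subtype indicators against the CNL
    reference (the largest group).  Rows with missing values in any used
    field are dropped by the caller.
    """
    df = pd.DataFrame(index=clinical.index)
    df["age_ge_55"] = (clinical["age"].astype(float) >= 55).astype(int)
    df["later_stage"] = clinical["stage"].isin(["III", "IV"]).astype(int)
    df["lvsi_positive"] = (clinical["lvsi"] == "yes").astype(int)
    lab = pd.Series({k: v for k, v in labels.items()}).reindex(clinical.index)
    for subtype in ("POLE", "MSI-H", "CNH"):
        df[f"subtype_{subtype}"] = (lab == subtype).astype(int)
    return df
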