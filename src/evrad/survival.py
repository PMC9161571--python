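"""Kaplan-Meier / log-rank stratification and Cox proportional-hazards models.

Backed by lifelines (Efron tie handling, the lifelines default, is used
throughout). Curves follow the reporting convention of the survival
figures: at-risk counts every 6 months and landmark survival at 12 and
24 months. The multivariate model uses backward stepwise selection,
iteratively removing the covariate with the largest Wald p-value above
``removal_alpha`` (default 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, ValidationError

DEFAULT_REMOVAL_ALPHA = 0.10


@dataclass
class KMCurve:
    """Product-limit survival curve with figure-style summaries."""

    times: np.ndarray
    survival: np.ndarray
    at_risk_ticks: dict[float, int]
    landmark_12m: float
    landmark_24m: float
    median_months: float


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference."""

    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    retained: list[str]
    removal_trace: list[tuple[str, float]] = field(default_factory=list)


def _check_times_events(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.size == 0 or t.size != e.size:
        raise ValidationError("times and events must be non-empty and aligned")
    if (t < 0).any():
        raise ValidationError("times must be nonnegative")
    return t, e


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set without contributing an event.
    ``median_months`` is +inf when the curve never crosses 0.5.
    """
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    ticks = np.arange(0.0, t.max() + 6.0, 6.0)
    at_risk = {float(tick): int((t >= tick).sum()) for tick in ticks}
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk_ticks=at_risk,
        landmark_12m=float(kmf.predict(12.0)),
        landmark_24m=float(kmf.predict(24.0)),
        median_months=float(kmf.median_survival_time_),
    )


def logrank_test(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test (O-E statistic, 1 df chi-square)."""
    t, e = _check_times_events(times, events)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels.size}")
    m = g == labels[0]
    res = _ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times: np.ndarray, events: np.ndarray, covariates: pd.DataFrame
) -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood (Efron ties)."""
    t, e = _check_times_events(times, events)
    X = pd.DataFrame(covariates).reset_index(drop=True)
    if len(X) != t.size:
        raise ValidationError("covariate rows must align with times")
    if t.size < 10:
        raise ValidationError("Cox fit requires n >= 10")
    if e.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    if X.shape[1] == 0:
        raise ValidationError("no covariates supplied")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValidationError(f"covariate '{col}' is constant")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except (_LLConvergence, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxResult(
        hazard_ratios={c: float(summary.loc[c, "exp(coef)"]) for c in X.columns},
        ci_lower={c: float(summary.loc[c, "exp(coef) lower 95%"]) for c in X.columns},
        ci_upper={c: float(summary.loc[c, "exp(coef) upper 95%"]) for c in X.columns},
        p_values={c: float(summary.loc[c, "p"]) for c in X.columns},
        log_likelihood=float(cph.log_likelihood_),
        retained=list(X.columns),
    )


def cox_backward_stepwise(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
    removal_alpha: float = DEFAULT_REMOVAL_ALPHA,
) -> CoxResult:
    """Backward stepwise Cox model.

    Starting from the full model, the covariate with the largest Wald
    p-value above ``removal_alpha`` is removed and the model refit, until
    every retained covariate has p <= removal_alpha (or none remain).
    The removal order and p-values are recorded in ``removal_trace``.
    """
    X = pd.DataFrame(covariates)
    trace: list[tuple[str, float]] = []
    result = cox_fit(times, events, X)
    while result.p_values:
        worst = max(result.p_values, key=result.p_values.get)
        worst_p = result.p_values[worst]
        if worst_p <= removal_alpha:
            break
        trace.append((worst, worst_p))
        X = X.drop(columns=[worst])
        if X.shape[1] == 0:
            result = CoxResult(
                hazard_ratios={},
                ci_lower={},
                ci_upper={},
                p_values={},
                log_likelihood=float("nan"),
                retained=[],
            )
            break
        result = cox_fit(times, events, X)
    result.removal_trace = trace
    return result
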