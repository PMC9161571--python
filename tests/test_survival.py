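"""Kaplan-Meier, log-rank and Cox proportional-hazards models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evrad import (
    SimulationConfig,
    cox_backward_stepwise,
    cox_fit,
    km_estimate,
    logrank_test,
    simulate_cohort,
)
from evrad.errors import ValidationError

from .oracles import logrank_bruteforce


def _surv_at(curve, t):
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return curve.survival[idx]


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

def test_km_all_censored_is_flat():
    curve = km_estimate([3.0, 5.0, 8.0], [False, False, False])
    assert np.all(curve.survival == 1.0)
    assert curve.median_months == np.inf


def test_km_three_events_by_hand():
    curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
    assert _surv_at(curve, 1.0) == pytest.approx(2 / 3)
    assert _surv_at(curve, 2.0) == pytest.approx(1 / 3)
    assert _surv_at(curve, 3.0) == pytest.approx(0.0)


def test_km_with_censoring_by_hand():
    """{1, 2+, 3}: risk set of 1 at t=3, so S drops 2/3 -> 0."""
    curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
    assert _surv_at(curve, 1.0) == pytest.approx(2 / 3)
    assert _surv_at(curve, 2.5) == pytest.approx(2 / 3)
    assert _surv_at(curve, 3.0) == pytest.approx(0.0)


def test_km_equals_empirical_survival_without_censoring(rng):
    times = rng.exponential(10, size=200)
    curve = km_estimate(times, np.ones(200, bool))
    for t in (2.0, 5.0, 15.0):
        assert _surv_at(curve, t) == pytest.approx((times > t).mean(), abs=1e-12)


def test_km_summaries():
    times = np.array([2.0, 7.0, 13.0, 20.0, 26.0])
    curve = km_estimate(times, np.ones(5, bool))
    assert curve.at_risk_ticks[0.0] == 5
    assert curve.at_risk_ticks[6.0] == 4
    assert curve.at_risk_ticks[12.0] == 3
    assert curve.landmark_12m == pytest.approx(3 / 5)
    assert curve.landmark_24m == pytest.approx(1 / 5)
    assert curve.median_months == pytest.approx(13.0)


def test_km_empty_raises():
    with pytest.raises(ValidationError):
        km_estimate([], [])


# --------------------------------------------------------------------------
# log-rank
# --------------------------------------------------------------------------

def test_logrank_identical_groups():
    times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    events = np.ones(6, bool)
    group = np.array([0, 0, 0, 1, 1, 1])
    chi2, p = logrank_test(times, events, group)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_six_subject_hand_example():
    times = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 6.0])
    events = np.array([True, True, False, True, True, True])
    group = np.array([0, 0, 0, 1, 1, 1])
    chi2, _ = logrank_test(times, events, group)
    assert chi2 == pytest.approx(logrank_bruteforce(times, events, group), rel=1e-9)


def test_logrank_matches_oracle_on_simulated_data(rng):
    for _ in range(10):
        n = 60
        group = rng.random(n) < 0.5
        times = rng.exponential(np.where(group, 6, 10))
        events = rng.random(n) > 0.25
        if events.sum() == 0:
            continue
        chi2, _ = logrank_test(times, events, group.astype(int))
        assert chi2 == pytest.approx(logrank_bruteforce(times, events, group), rel=1e-6)
        assert chi2 >= 0


def test_logrank_p_uniform_under_null(rng):
    pvals = []
    for _ in range(1000):
        times = rng.exponential(10, size=100)
        events = rng.random(100) > 0.2
        group = (rng.random(100) < 0.5).astype(int)
        _, p = logrank_test(times, events, group)
        pvals.append(p)
    _, ks_p = sps.kstest(pvals, "uniform")
    assert ks_p > 0.01


def test_logrank_single_group_raises():
    with pytest.raises(ValidationError):
        logrank_test([1.0, 2.0], [True, True], [0, 0])


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

def test_cox_null_covariate_recovers_unity(rng):
    n = 2000
    x = (rng.random(n) < 0.5).astype(int)
    times = rng.exponential(10, size=n)
    events = np.ones(n, bool)
    res = cox_fit(times, events, pd.DataFrame({"x": x}))
    assert 0.9 < res.hazard_ratios["x"] < 1.1
    assert res.ci_lower["x"] < res.hazard_ratios["x"] < res.ci_upper["x"]


@pytest.mark.parametrize("true_hr", [0.35, 0.45, 1.0])
def test_cox_log_hr_recovery(true_hr, rng):
    n = 2000
    x = (rng.random(n) < 0.5).astype(int)
    times = rng.exponential(1.0 / (0.1 * true_hr**x))
    censor = rng.uniform(0, 30, n)
    events = times <= censor
    obs = np.minimum(times, censor)
    res = cox_fit(obs, events, pd.DataFrame({"x": x}))
    assert abs(np.log(res.hazard_ratios["x"]) - np.log(true_hr)) < 0.12


def test_cox_validation_errors():
    with pytest.raises(ValidationError):
        cox_fit([1.0] * 5, [True] * 5, pd.DataFrame({"x": range(5)}))  # n < 10
    with pytest.raises(ValidationError):
        cox_fit(
            np.arange(12, dtype=float),
            np.zeros(12, bool),
            pd.DataFrame({"x": np.arange(12)}),
        )  # no events
    with pytest.raises(ValidationError):
        cox_fit(
            np.arange(1, 13, dtype=float),
            np.ones(12, bool),
            pd.DataFrame({"x": np.ones(12)}),
        )  # constant covariate


def test_cox_fit_beats_null_partial_likelihood(rng):
    """The maximized partial likelihood never sits below the beta=0 value.

    The null partial log-likelihood of an exponential-rank model is
    computed directly from the risk sets (an independent closed form).
    """
    n = 200
    x = rng.normal(size=n)
    times = rng.exponential(np.exp(-0.5 * x) * 10)
    res = cox_fit(times, np.ones(n, bool), pd.DataFrame({"x": x}))
    # beta = 0: each event contributes -log(|risk set|); no ties here
    null_ll = -np.sum(np.log(np.arange(n, 0, -1, dtype=float)))
    assert np.isfinite(res.log_likelihood)
    assert res.log_likelihood >= null_ll


def test_stepwise_single_covariate_equals_plain_fit(rng):
    n = 100
    x = (rng.random(n) < 0.5).astype(int)
    times = rng.exponential(10 * 0.5**x)
    res_a = cox_fit(times, np.ones(n, bool), pd.DataFrame({"x": x}))
    res_b = cox_backward_stepwise(times, np.ones(n, bool), pd.DataFrame({"x": x}))
    assert res_b.retained == ["x"]
    assert res_b.hazard_ratios["x"] == pytest.approx(res_a.hazard_ratios["x"])


def test_stepwise_null_retention_rate(rng):
    """Pure-noise covariates are retained at roughly the removal alpha (0.10)."""
    k, reps, retained = 5, 30, 0
    for _ in range(reps):
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{j}" for j in range(k)])
        times = rng.exponential(10, size=n)
        res = cox_backward_stepwise(times, np.ones(n, bool), X, removal_alpha=0.10)
        retained += len(res.retained)
    mean_retained = retained / reps
    assert 0.05 <= mean_retained <= 1.5  # expectation ~ 0.1 * k = 0.5


def test_stepwise_keeps_true_signal(rng):
    hits = 0
    for _ in range(20):
        n = 1000
        x_true = (rng.random(n) < 0.5).astype(int)
        X = pd.DataFrame(
            {
                "true": x_true,
                **{f"noise{j}": rng.normal(size=n) for j in range(4)},
            }
        )
        times = rng.exponential(10 * 0.45**x_true)
        res = cox_backward_stepwise(times, np.ones(n, bool), X)
        hits += "true" in res.retained
    assert hits >= 19  # >= 95% retention


def test_cox_hr_recovery_on_simulated_cohort():
    """Generator + Cox round trip at the configured hazard ratios."""
    cfg = SimulationConfig(
        n_patients=2000, censor_fraction=0.2, band_noise_cv=0.0, seed=23
    )
    records, blots = simulate_cohort(cfg)
    from evrad import compute_delta

    dec = np.array(
        [int(compute_delta(b).dynamics_class == "decrease") for b in blots]
    )
    for endpoint, true_hr in (("pfs", cfg.true_hr_pfs), ("os", cfg.true_hr_os)):
        times = np.array([getattr(r, f"{endpoint}_months") for r in records])
        events = np.array([getattr(r, f"{endpoint}_event") for r in records])
        res = cox_fit(times, events, pd.DataFrame({"dec": dec}))
        assert abs(np.log(res.hazard_ratios["dec"]) - np.log(true_hr)) < 0.15
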