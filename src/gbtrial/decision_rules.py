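"""Interim stopping rules and the end-of-trial effectiveness declaration.

Effectiveness at the end of the trial is declared when
P(beta < 0 | all data) > Delta.  At interims, two Monte-Carlo
expectations of that indicator are formed over B completed versions of
the current data:

* *expected effectiveness* — impute only the pending (enrolled,
  unresolved) subjects; stop for effectiveness when the mean indicator
  exceeds Delta_e;
* *futility* — additionally simulate arms and outcomes for everyone
  not yet enrolled up to the maximum sample size; stop for futility
  when the mean indicator falls below Delta_f.

Each of the B repetitions uses a fresh theta draw from the imputation
posterior, so the Monte-Carlo average integrates over both outcome and
parameter uncertainty.  Effectiveness is checked before futility;
both expectations are always computed for logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gb_inference import PosteriorSummary, SurvivalSample
from .predictive_imputation import (
    HorizonRules,
    InterimDataset,
    impute_pending,
    simulate_future_cohort,
)

__all__ = [
    "DecisionThresholds",
    "InterimDecision",
    "final_effectiveness",
    "expected_effectiveness",
    "expected_futility",
    "evaluate_interim",
    "interim_log_frame",
]


def interim_log_frame(decisions):
    """Tidy per-interim decision log (one row per analysis)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "k": d.calendar_time,
            "n_enrolled": d.n_enrolled,
            "n_pending": d.n_pending,
            "expected_effectiveness": d.expected_effectiveness,
            "futility_expectation": d.futility_expectation,
            "action": d.action,
        }
        for d in decisions
    ])


@dataclass(frozen=True)
class DecisionThresholds:
    """Trial decision thresholds (ORVAC defaults).

    ``delta`` — final effectiveness threshold on P(beta<0);
    ``delta_e`` / ``delta_f`` — interim expected-effectiveness and
    futility thresholds; ``B`` — inner Monte-Carlo repetitions.
    """

    delta: float = 0.97
    delta_e: float = 0.90
    delta_f: float = 0.05
    B: int = 100

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")
        # closed outer ends let a rule be switched off (delta_e=1 / delta_f=0
        # can never trigger, since the comparisons are strict)
        if not 0.0 < self.delta_e <= 1.0:
            raise ValueError(f"delta_e must lie in (0, 1], got {self.delta_e}")
        if not 0.0 <= self.delta_f < 1.0:
            raise ValueError(f"delta_f must lie in [0, 1), got {self.delta_f}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class InterimDecision:
    """Outcome of one interim analysis."""

    expected_effectiveness: float
    futility_expectation: float
    action: str  # stop_effective | stop_futile | continue
    eff_indicators: np.ndarray = field(repr=False, default=None)
    fut_indicators: np.ndarray = field(repr=False, default=None)
    calendar_time: float = float("nan")
    n_enrolled: int = 0
    n_pending: int = 0


def final_effectiveness(data: SurvivalSample, analysis_model, thresholds: DecisionThresholds):
    """End-of-trial declaration: P(beta<0|data) > Delta (strict)."""
    posterior = analysis_model.posterior(data)
    if posterior.degenerate:
        return False, posterior
    return bool(posterior.prob_lt_zero > thresholds.delta), posterior


def expected_effectiveness(
    interim: InterimDataset,
    analysis_model,
    imputer,
    thresholds: DecisionThresholds,
    horizon: HorizonRules,
    rng,
) -> np.ndarray:
    """B indicator draws of I(P(beta<0 | exited + imputed pending) > Delta)."""
    rng = np.random.default_rng(rng)
    if interim.n_pending == 0:
        post = analysis_model.posterior(interim.exited)
        ind = int((not post.degenerate) and post.prob_lt_zero > thresholds.delta)
        return np.full(thresholds.B, ind, dtype=int)
    indicators = np.empty(thresholds.B, dtype=int)
    for b in range(thresholds.B):
        spec = imputer.draw_spec(rng)
        completed = impute_pending(interim, spec, horizon, rng)
        post = analysis_model.posterior(completed.completed)
        indicators[b] = int((not post.degenerate) and post.prob_lt_zero > thresholds.delta)
    return indicators


def expected_futility(
    interim: InterimDataset,
    analysis_model,
    imputer,
    thresholds: DecisionThresholds,
    n_max: int,
    horizon: HorizonRules,
    rng,
    allocation_p: float = 0.5,
    cohort_size: int = 50,
    period_months: float = 3.0,
    age_range=(6.0, 12.0),
) -> np.ndarray:
    """B indicator draws over imputed pending *and* simulated future cohorts."""
    if interim.n_enrolled > n_max:
        raise ValueError("enrolled more than n_max")
    rng = np.random.default_rng(rng)
    n_future = n_max - interim.n_enrolled
    if interim.n_pending == 0 and n_future == 0:
        post = analysis_model.posterior(interim.exited)
        ind = int((not post.degenerate) and post.prob_lt_zero > thresholds.delta)
        return np.full(thresholds.B, ind, dtype=int)
    indicators = np.empty(thresholds.B, dtype=int)
    for b in range(thresholds.B):
        spec = imputer.draw_spec(rng)
        completed = impute_pending(interim, spec, horizon, rng)
        _, future = simulate_future_cohort(
            interim, spec, n_future, horizon, rng,
            allocation_p=allocation_p, cohort_size=cohort_size,
            period_months=period_months, age_range=age_range,
        )
        data = SurvivalSample.concat(completed.completed, future)
        post = analysis_model.posterior(data)
        indicators[b] = int((not post.degenerate) and post.prob_lt_zero > thresholds.delta)
    return indicators


def evaluate_interim(
    interim: InterimDataset,
    analysis_model,
    imputer,
    thresholds: DecisionThresholds,
    n_max: int,
    horizon: HorizonRules,
    rng,
    **future_kwargs,
) -> InterimDecision:
    """Run both interim rules and resolve the action (effectiveness first)."""
    rng = np.random.default_rng(rng)
    eff = expected_effectiveness(interim, analysis_model, imputer, thresholds, horizon, rng)
    fut = expected_futility(
        interim, analysis_model, imputer, thresholds, n_max, horizon, rng, **future_kwargs
    )
    eff_est = float(eff.mean())
    fut_est = float(fut.mean())
    if eff_est > thresholds.delta_e:
        action = "stop_effective"
    elif fut_est < thresholds.delta_f:
        action = "stop_futile"
    else:
        action = "continue"
    return InterimDecision(
        expected_effectiveness=eff_est,
        futility_expectation=fut_est,
        action=action,
        eff_indicators=eff,
        fut_indicators=fut,
        calendar_time=interim.calendar_time,
        n_enrolled=interim.n_enrolled,
        n_pending=interim.n_pending,
    )
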