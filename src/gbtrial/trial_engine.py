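"""Time-stepped simulation of one adaptive (or fixed-sample) trial.

Calendar time advances in 1-month increments.  Cohorts enroll at the
start of each enrollment block (ORVAC: 50 participants every 3 months,
ages Uniform(6, 12) months, 1:1 randomization); each participant's
latent event time is drawn once at enrollment from the data-generating
hazard and never changes — only its censoring status does as the trial
clock advances.  An interim analysis runs at the first month at which
cumulative enrollment reaches the next scheduled count (ORVAC: 250,
then every 50).  At an interim, subjects are split into exited
(event observed, or follow-up exhausted by the 36-months-of-age cap /
trial horizon) and pending (administratively censored at their elapsed
time), the imputation model is refitted, and the expected-effectiveness
and futility rules are evaluated.  On stopping — or when the maximum
sample size is reached — every enrolled participant is followed to the
end of their follow-up window and the final effectiveness declaration
is computed (analysis at the stop date is available as a config flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .decision_rules import DecisionThresholds, InterimDecision, evaluate_interim, final_effectiveness
from .gb_inference import PosteriorSummary, SurvivalSample
from .hazard_models import HazardSpec, sample_event_time
from .predictive_imputation import HorizonRules, InterimDataset, fit_imputation_model

__all__ = [
    "TrialDesignConfig",
    "ParticipantRecord",
    "TrialResult",
    "run_adaptive_trial",
    "run_fixed_trial",
]

#: analysis-model name -> default imputation model family
_DEFAULT_IMPUTATION = {
    "exp": "exponential",
    "exponential": "exponential",
    "weib": "weibull",
    "weibull": "weibull",
    "peh": "piecewise",
    "piecewise": "piecewise",
    "gb": "super",
}


@dataclass(frozen=True)
class TrialDesignConfig:
    """Adaptive design parameters (defaults are the ORVAC design)."""

    n_max: int = 1000
    cohort_size: int = 50
    period_months: float = 3.0
    first_interim: int = 250
    interim_step: int = 50
    age_range: tuple = (6.0, 12.0)
    age_cap: Optional[float] = 36.0
    horizon: Optional[float] = None  # calendar end of trial, months
    allocation_p: float = 0.5
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    analysis_at_stop: bool = False
    imputation_model: Optional[str] = None  # default: per analysis model
    imputation_mcmc_iter: int = 2000
    imputation_mcmc_burn: int = 500

    def __post_init__(self):
        if self.n_max < 2 or self.cohort_size < 1 or self.interim_step < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.allocation_p < 1.0:
            raise ValueError("allocation_p must be in (0, 1)")
        if self.first_interim > self.n_max:
            raise ValueError("first interim beyond n_max")
        if self.age_cap is None and self.horizon is None:
            raise ValueError("need an age cap or a trial horizon to end follow-up")

    @property
    def horizon_rules(self) -> HorizonRules:
        return HorizonRules(age_cap=self.age_cap, trial_end=self.horizon)


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's trajectory through the trial."""

    id: int
    enroll_time: float
    age_at_enroll: float
    arm: int
    event_time_latent: float  # months from enrollment; +inf = never within support
    observed_time: float
    event: int
    censor_reason: str  # none | age_cap | trial_end | interim_admin


@dataclass
class TrialResult:
    """Trajectory and conclusion of one simulated trial."""

    stop_reason: str  # effective | futile | max_n
    n_enrolled: int
    interim_log: List[InterimDecision]
    final_declared_effective: bool
    final_posterior: PosteriorSummary
    seed: object = None
    participants: Optional[List[ParticipantRecord]] = None

    @property
    def n_interims(self) -> int:
        return len(self.interim_log)

    @property
    def last_expected_effectiveness(self) -> float:
        return self.interim_log[-1].expected_effectiveness if self.interim_log else float("nan")

    @property
    def last_futility_expectation(self) -> float:
        return self.interim_log[-1].futility_expectation if self.interim_log else float("nan")


class _Population:
    """Columnar store of enrolled participants."""

    def __init__(self):
        self.enroll_time = np.empty(0)
        self.age = np.empty(0)
        self.arm = np.empty(0, dtype=int)
        self.latent = np.empty(0)

    def __len__(self):
        return self.enroll_time.size

    def enroll(self, k, m, generator: HazardSpec, age_range, allocation_p, rng):
        ages = rng.uniform(age_range[0], age_range[1], size=m)
        arms = (rng.uniform(size=m) < allocation_p).astype(int)
        u = rng.uniform(size=m)
        latent = np.atleast_1d(sample_event_time(generator, arms, u))
        self.enroll_time = np.concatenate([self.enroll_time, np.full(m, float(k))])
        self.age = np.concatenate([self.age, ages])
        self.arm = np.concatenate([self.arm, arms])
        self.latent = np.concatenate([self.latent, latent])

    def follow_up_cap(self, horizon: HorizonRules, t_max: float):
        return np.minimum(horizon.follow_up_cap(self.age, self.enroll_time), t_max)

    def snapshot(self, k: float, horizon: HorizonRules, t_max: float) -> InterimDataset:
        """Split into exited / pending at calendar time k."""
        elapsed = k - self.enroll_time
        cap = self.follow_up_cap(horizon, t_max)
        had_event = self.latent <= np.minimum(elapsed, cap)
        fu_done = cap <= elapsed
        exited_mask = had_event | fu_done
        obs = np.where(had_event, self.latent, cap)
        exited = SurvivalSample(
            obs[exited_mask], had_event[exited_mask].astype(int), self.arm[exited_mask]
        )
        pend = ~exited_mask
        return InterimDataset(
            exited=exited,
            pending_y_star=elapsed[pend],
            pending_arms=self.arm[pend],
            pending_age_at_enroll=self.age[pend],
            pending_enroll_time=self.enroll_time[pend],
            calendar_time=float(k),
        )

    def complete_follow_up(self, horizon: HorizonRules, t_max: float) -> SurvivalSample:
        cap = self.follow_up_cap(horizon, t_max)
        observed = np.minimum(self.latent, cap)
        events = (self.latent <= cap).astype(int)
        return SurvivalSample(observed, events, self.arm)

    def records(self, horizon: HorizonRules, t_max: float) -> List[ParticipantRecord]:
        data = self.complete_follow_up(horizon, t_max)
        caps = self.follow_up_cap(horizon, t_max)
        out = []
        for i in range(len(self)):
            if data.events[i]:
                reason = "none"
            elif horizon.age_cap is not None and np.isclose(caps[i], horizon.age_cap - self.age[i]):
                reason = "age_cap"
            else:
                reason = "trial_end"
            out.append(
                ParticipantRecord(
                    id=i,
                    enroll_time=float(self.enroll_time[i]),
                    age_at_enroll=float(self.age[i]),
                    arm=int(self.arm[i]),
                    event_time_latent=float(self.latent[i]),
                    observed_time=float(data.times[i]),
                    event=int(data.events[i]),
                    censor_reason=reason,
                )
            )
        return out


def run_adaptive_trial(
    design: TrialDesignConfig,
    generator: HazardSpec,
    analysis_model,
    rng_seed=None,
    keep_participants: bool = False,
    interim_callback=None,
) -> TrialResult:
    """Simulate one adaptive trial under ``generator`` and ``analysis_model``.

    ``interim_callback(interim_dataset, decision)``, when given, is
    invoked after each interim — handy for inspecting censoring
    bookkeeping in tests.
    """
    rng = np.random.default_rng(rng_seed)
    horizon = design.horizon_rules
    pop = _Population()
    thresholds = design.thresholds
    imput_model = design.imputation_model or _DEFAULT_IMPUTATION.get(
        getattr(analysis_model, "name", "gb"), "super"
    )
    t_max = generator.t_max

    next_interim = design.first_interim
    interim_log: List[InterimDecision] = []
    stop_reason = "max_n"
    k = 0
    max_months = int(
        np.ceil(design.n_max / design.cohort_size) * design.period_months + 2
    )
    while k <= max_months:
        if k % design.period_months == 0 and len(pop) < design.n_max:
            m = min(design.cohort_size, design.n_max - len(pop))
            pop.enroll(k, m, generator, design.age_range, design.allocation_p, rng)
        if len(pop) >= next_interim and next_interim < design.n_max:
            # analysis at the end of the month in which enrollment
            # crossed the threshold: elapsed time is (k+1) - enroll_time
            interim = pop.snapshot(k + 1.0, horizon, t_max)
            imputer = fit_imputation_model(
                interim,
                model=imput_model,
                rng_seed=int(rng.integers(2**31)),
                t_max=max(t_max, 40.0),
                n_iter=design.imputation_mcmc_iter,
                burn=design.imputation_mcmc_burn,
            )
            decision = evaluate_interim(
                interim, analysis_model, imputer, thresholds, design.n_max, horizon,
                rng, allocation_p=design.allocation_p,
                cohort_size=design.cohort_size, period_months=design.period_months,
                age_range=design.age_range,
            )
            interim_log.append(decision)
            if interim_callback is not None:
                interim_callback(interim, decision)
            if decision.action == "stop_effective":
                stop_reason = "effective"
                break
            if decision.action == "stop_futile":
                stop_reason = "futile"
                break
            next_interim += design.interim_step
        if len(pop) >= design.n_max and next_interim >= design.n_max:
            break
        k += 1

    if design.analysis_at_stop and stop_reason in ("effective", "futile"):
        final_data = pop.snapshot(k + 1.0, horizon, t_max).as_censored_sample()
    else:
        final_data = pop.complete_follow_up(horizon, t_max)
    declared, posterior = final_effectiveness(final_data, analysis_model, thresholds)
    return TrialResult(
        stop_reason=stop_reason,
        n_enrolled=len(pop),
        interim_log=interim_log,
        final_declared_effective=declared,
        final_posterior=posterior,
        seed=rng_seed,
        participants=pop.records(horizon, t_max) if keep_participants else None,
    )


def run_fixed_trial(
    n: int,
    horizon: Optional[float],
    generator: HazardSpec,
    analysis_model,
    rng_seed=None,
    thresholds: DecisionThresholds = DecisionThresholds(delta=0.975),
    age_range: Optional[tuple] = None,
    age_cap: Optional[float] = None,
    allocation_p: float = 0.5,
    keep_participants: bool = False,
) -> TrialResult:
    """Fixed-sample trial: everyone enrolls at time 0, no interims.

    With ``horizon`` set, subjects are right-censored at the end of the
    trial; with ``age_range``/``age_cap`` set, each subject gets an
    enrollment age and is followed until the age cap (ORVAC-style).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if horizon is None and age_cap is None:
        raise ValueError("need a horizon or an age cap")
    rng = np.random.default_rng(rng_seed)
    pop = _Population()
    hrules = HorizonRules(age_cap=age_cap, trial_end=horizon)
    pop.enroll(0, n, generator, age_range or (0.0, 0.0), allocation_p, rng)
    final_data = pop.complete_follow_up(hrules, generator.t_max)
    declared, posterior = final_effectiveness(final_data, analysis_model, thresholds)
    return TrialResult(
        stop_reason="max_n",
        n_enrolled=n,
        interim_log=[],
        final_declared_effective=declared,
        final_posterior=posterior,
        seed=rng_seed,
        participants=pop.records(hrules, generator.t_max) if keep_participants else None,
    )
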