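"""Posterior-predictive completion of an interim trial snapshot.

At an interim analysis the enrolled participants split into those who
have *exited* (event observed, or censored for a reason other than the
analysis date) and those still *pending*: enrolled for ``y*`` months
with no event yet.  To evaluate stopping rules, pending outcomes ``z``
are imputed from the left-truncated posterior predictive distribution

    p(z | theta, x) / (1 - F_Z(y* | theta, x)),   z > y*,

with theta drawn from the posterior of a designated imputation model
fitted to the interim data (pending subjects entering as censored at
``y*``).  The futility rule additionally needs outcomes ``w`` and arms
``v`` for participants not yet enrolled, drawn unconditionally from the
same theta with arms following the randomization scheme.

All imputed and simulated outcomes are re-censored by the applicable
horizon rules: months of follow-up remaining before the participant
turns 36 months old, and (when configured) the trial's calendar end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .gb_inference import SurvivalSample
from .hazard_models import HazardSpec, sample_event_time, sample_truncated_event_time
from .parametric_inference import ParametricPosterior, fit_parametric

__all__ = [
    "HorizonRules",
    "InterimDataset",
    "ImputedDataset",
    "Imputer",
    "FixedImputer",
    "fit_imputation_model",
    "impute_pending",
    "simulate_future_cohort",
]


@dataclass(frozen=True)
class HorizonRules:
    """Censoring limits applied to imputed/simulated outcomes.

    ``age_cap`` is the follow-up limit in months of age (36 for ORVAC);
    ``trial_end`` an optional calendar stop time.  ``None`` disables a
    rule.
    """

    age_cap: Optional[float] = 36.0
    trial_end: Optional[float] = None

    def follow_up_cap(self, age_at_enroll, enroll_time):
        """Maximum observable time-on-study per subject (may be +inf)."""
        cap = np.full(np.broadcast(np.asarray(age_at_enroll), np.asarray(enroll_time)).shape, np.inf)
        if self.age_cap is not None:
            cap = np.minimum(cap, self.age_cap - np.asarray(age_at_enroll, dtype=float))
        if self.trial_end is not None:
            cap = np.minimum(cap, self.trial_end - np.asarray(enroll_time, dtype=float))
        return cap


@dataclass(frozen=True)
class InterimDataset:
    """Split of trial data at one interim analysis.

    ``exited`` holds completed records; the ``pending_*`` arrays
    describe subjects censored purely by the analysis date, with
    ``pending_y_star`` their event-free elapsed time.
    """

    exited: SurvivalSample
    pending_y_star: np.ndarray
    pending_arms: np.ndarray
    pending_age_at_enroll: np.ndarray
    pending_enroll_time: np.ndarray
    calendar_time: float

    def __post_init__(self):
        ys = np.asarray(self.pending_y_star, dtype=float)
        xs = np.asarray(self.pending_arms, dtype=np.int64)
        ages = np.asarray(self.pending_age_at_enroll, dtype=float)
        et = np.asarray(self.pending_enroll_time, dtype=float)
        if not (ys.shape == xs.shape == ages.shape == et.shape):
            raise ValueError("pending arrays must have equal length")
        if np.any(ys < 0):
            raise ValueError("pending elapsed times must be >= 0")
        for name, arr in (
            ("pending_y_star", ys), ("pending_arms", xs),
            ("pending_age_at_enroll", ages), ("pending_enroll_time", et),
        ):
            object.__setattr__(self, name, arr)

    @property
    def n_pending(self) -> int:
        return self.pending_y_star.size

    @property
    def n_enrolled(self) -> int:
        return len(self.exited) + self.n_pending

    def as_censored_sample(self) -> SurvivalSample:
        """Interim data with pending subjects censored at y* (for fitting)."""
        pending = SurvivalSample(
            self.pending_y_star, np.zeros(self.n_pending, dtype=int), self.pending_arms
        )
        return SurvivalSample.concat(self.exited, pending)


@dataclass(frozen=True)
class ImputedDataset:
    """One completed data set: exited + imputed pending (+ future cohort)."""

    completed: SurvivalSample
    n_imputed: int
    n_future: int = 0


# ---------------------------------------------------------------------------
# theta sources


class Imputer:
    """Draws data-generating specs from a fitted parametric posterior."""

    def __init__(self, posterior: ParametricPosterior):
        self.posterior = posterior

    def draw_spec(self, rng) -> HazardSpec:
        return self.posterior.spec_for(self.posterior.sample_theta(rng))


class FixedImputer:
    """Imputer that always returns one fixed spec (no theta uncertainty)."""

    def __init__(self, spec: HazardSpec):
        self.spec = spec

    def draw_spec(self, rng) -> HazardSpec:
        return self.spec


def fit_imputation_model(
    interim: InterimDataset,
    model: str = "super",
    priors: Optional[dict] = None,
    rng_seed=None,
    t_max: float = 40.0,
    n_iter: int = 3000,
    burn: int = 1000,
    **kwargs,
) -> Imputer:
    """Fit the imputation model to interim data and wrap it as an Imputer.

    The default imputation model is the flexible super model updated by
    standard Bayesian inference with its knot values free; parametric
    analyses typically pass their own family instead.
    """
    data = interim.as_censored_sample()
    fit = fit_parametric(
        model, data, priors=priors, rng_seed=rng_seed, t_max=t_max,
        n_iter=n_iter, burn=burn, **kwargs,
    )
    return Imputer(fit)


# ---------------------------------------------------------------------------
# operations


def _censor(times_latent, cap, t_max):
    """Apply per-subject follow-up caps; +inf latent times are censored."""
    cap_eff = np.minimum(cap, t_max)
    observed = np.minimum(times_latent, cap_eff)
    events = (times_latent <= cap_eff).astype(int)
    return observed, events


def dump_completed_csv(dataset: ImputedDataset, path) -> None:
    """Debug helper: write a completed data set to CSV."""
    import pandas as pd

    pd.DataFrame({
        "time": dataset.completed.times,
        "event": dataset.completed.events,
        "arm": dataset.completed.arms,
    }).to_csv(path, index=False)


def impute_pending(
    interim: InterimDataset,
    spec: HazardSpec,
    horizon: HorizonRules,
    rng,
) -> ImputedDataset:
    """Impute left-truncated outcomes for all pending subjects under ``spec``.

    Each pending subject's z is drawn conditional on z > y*, then
    censored at the minimum of the subject's remaining follow-up (age
    cap / trial end) and the spec's support horizon.  Subjects with no
    follow-up remaining keep their record censored at y*.
    """
    rng = np.random.default_rng(rng)
    m = interim.n_pending
    if m == 0:
        return ImputedDataset(completed=interim.exited, n_imputed=0)

    ys = interim.pending_y_star
    cap = horizon.follow_up_cap(interim.pending_age_at_enroll, interim.pending_enroll_time)
    cap_eff = np.minimum(cap, spec.t_max)
    times = ys.copy()
    events = np.zeros(m, dtype=int)

    open_fu = (cap_eff > ys) & (ys < spec.t_max)
    if np.any(open_fu):
        u = rng.uniform(size=int(open_fu.sum()))
        z = sample_truncated_event_time(
            spec, interim.pending_arms[open_fu], ys[open_fu], u
        )
        obs, ev = _censor(np.atleast_1d(z), cap_eff[open_fu], spec.t_max)
        times[open_fu] = obs
        events[open_fu] = ev
    # no-follow-up-left subjects stay censored at y*

    imputed = SurvivalSample(times, events, interim.pending_arms)
    return ImputedDataset(
        completed=SurvivalSample.concat(interim.exited, imputed), n_imputed=m
    )


def simulate_future_cohort(
    interim: InterimDataset,
    spec: HazardSpec,
    n_future: int,
    horizon: HorizonRules,
    rng,
    allocation_p: float = 0.5,
    cohort_size: int = 50,
    period_months: float = 3.0,
    age_range=(6.0, 12.0),
) -> tuple[np.ndarray, SurvivalSample]:
    """Simulate arms and outcomes for participants not yet enrolled.

    Arms are i.i.d. Bernoulli(allocation_p); enrollment continues the
    trial's schedule (``cohort_size`` per ``period_months``) from the
    next scheduled block after the interim; ages are Uniform over
    ``age_range``.  Returns the arm vector v and the censored sample w.
    """
    if n_future < 0:
        raise ValueError("n_future must be >= 0")
    rng = np.random.default_rng(rng)
    if n_future == 0:
        empty = SurvivalSample(np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int))
        return np.empty(0, dtype=int), empty

    arms = (rng.uniform(size=n_future) < allocation_p).astype(int)
    ages = rng.uniform(age_range[0], age_range[1], size=n_future)
    next_block = period_months * (np.floor(interim.calendar_time / period_months) + 1.0)
    block_idx = np.arange(n_future) // cohort_size
    enroll = next_block + period_months * block_idx

    u = rng.uniform(size=n_future)
    latent = np.atleast_1d(sample_event_time(spec, arms, u))
    cap = np.maximum(horizon.follow_up_cap(ages, enroll), 0.0)
    observed, events = _censor(latent, cap, spec.t_max)
    return arms, SurvivalSample(observed, events, arms)
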