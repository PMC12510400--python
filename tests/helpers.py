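"""Shared oracles and simulation helpers for the test suite.

Everything here is deliberately independent of the library's optimized
code paths: the partial-likelihood oracle enumerates risk sets per
event, and the MPLE solver is a plain Newton iteration on the score.
"""

import numpy as np

from gbtrial import SurvivalSample, sample_event_time


def simulate_sample(spec, n, rng, censor_time=None, age_cap=None, age_range=(6.0, 12.0),
                    allocation_p=0.5) -> SurvivalSample:
    """Draw a censored two-arm sample from a hazard spec."""
    arms = (rng.uniform(size=n) < allocation_p).astype(int)
    u = rng.uniform(size=n)
    latent = np.atleast_1d(sample_event_time(spec, arms, u))
    cap = np.full(n, spec.t_max)
    if censor_time is not None:
        cap = np.minimum(cap, censor_time)
    if age_cap is not None:
        ages = rng.uniform(age_range[0], age_range[1], size=n)
        cap = np.minimum(cap, age_cap - ages)
    observed = np.minimum(latent, cap)
    events = (latent <= cap).astype(int)
    return SurvivalSample(observed, events, arms)


def naive_partial_loss(data: SurvivalSample, beta: float) -> float:
    """Per-event enumeration of the negative partial log-likelihood.

    Breslow convention: the risk set of event i is every subject with
    observed time >= t_i (censored-at-t_i subjects included); tied
    events each contribute with that shared risk set.
    """
    loss = 0.0
    for i in range(len(data)):
        if data.events[i] != 1:
            continue
        risk = data.times >= data.times[i]
        denom = np.sum(np.exp(data.arms[risk] * beta))
        loss -= data.arms[i] * beta - np.log(denom)
    return float(loss)


def newton_mple(data: SurvivalSample, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Maximum partial-likelihood estimate via Newton iteration.

    Works on the score of the enumerated partial log-likelihood; returns
    nan for degenerate data (no events, or a risk-set arm monotone so
    the MPLE diverges past |beta| = 20).
    """
    ev = np.flatnonzero(data.events == 1)
    if ev.size == 0:
        return float("nan")
    beta = 0.0
    for _ in range(max_iter):
        score = 0.0
        info = 0.0
        for i in ev:
            risk = data.times >= data.times[i]
            w = np.exp(data.arms[risk] * beta)
            pbar = np.sum(w * data.arms[risk]) / np.sum(w)
            score += data.arms[i] - pbar
            info += pbar * (1.0 - pbar)
        if info <= 0:
            return float("nan")
        step = score / info
        beta += step
        if abs(beta) > 20:
            return float("nan")
        if abs(step) < tol:
            break
    return float(beta)


def random_survival_sample(rng, n=None, ties=False) -> SurvivalSample:
    """Small random dataset with mixed censoring (and optional ties)."""
    n = n or int(rng.integers(5, 201))
    arms = (rng.uniform(size=n) < 0.5).astype(int)
    times = rng.exponential(10.0, size=n) + 0.01
    if ties:
        times = np.round(times, 0) + 0.5
    events = (rng.uniform(size=n) < 0.7).astype(int)
    return SurvivalSample(times, events, arms)
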