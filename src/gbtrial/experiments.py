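"""Replicate batches over scenario grids and operating characteristics.

A scenario pairs a data-generating hazard (possibly drawn fresh from a
prior each replicate, e.g. the super-model prior or a uniform prior on
the log baseline rate), a treatment effect (fixed or uniform over an
interval), an analysis model, and a trial design (fixed-sample or
adaptive).  ``run_scenario`` simulates J independent trials with
counter-derived seeds — SeedSequence(base_seed, scenario_index,
replicate) — so results are invariant to execution order and worker
count, and aggregates declaration proportions, stopping proportions,
enrollment counts and estimation error of the posterior modes, each
with a Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .decision_rules import DecisionThresholds
from .gb_inference import GBConfig, GeneralBayesAnalysis
from .hazard_models import (
    HazardSpec,
    SuperModelSpec,
    exponential_spec,
    fit_super_coefficients,
    piecewise_spec,
    sample_super_model_prior,
    super_spec,
    weibull_spec,
)
from .parametric_inference import ExponentialAnalysis, PiecewiseAnalysis, WeibullAnalysis
from .trial_engine import TrialDesignConfig, run_adaptive_trial, run_fixed_trial

__all__ = [
    "ORVAC_BETA_GRID",
    "ScenarioConfig",
    "ScenarioSummary",
    "make_analysis",
    "run_scenario",
    "power_curve",
    "illustrative_scenario",
    "orvac_fixed_scenario",
    "orvac_range_scenario",
]

#: treatment-effect grid used throughout the ORVAC redesign scenarios
ORVAC_BETA_GRID = (0.0, -0.075, -0.125, -0.175, -0.25, -0.5)

_ANALYSES = {
    "exp": ExponentialAnalysis,
    "weib": WeibullAnalysis,
    "gb": GeneralBayesAnalysis,
    "peh": PiecewiseAnalysis,
}


def make_analysis(name: str, **kwargs):
    """Instantiate an analysis model by its short id (exp|weib|gb|peh)."""
    if name not in _ANALYSES:
        raise ValueError(f"unknown analysis model {name!r}; choose from {sorted(_ANALYSES)}")
    if name == "gb":
        return GeneralBayesAnalysis(GBConfig(**kwargs)) if kwargs else GeneralBayesAnalysis()
    return _ANALYSES[name](**kwargs)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``generator`` describes the data-generating model; per-replicate
    priors are expressed with range keys: ``log_rate_range`` for the
    exponential, ``value_range`` (+ ``knots``) for the super-model
    prior.  ``beta`` is a number or a (lo, hi) interval sampled
    uniformly per replicate.  ``scale`` multiplies J (and the inner B
    of adaptive designs) for desk-scale runs.
    """

    name: str = "scenario"
    generator: dict = field(default_factory=lambda: {"family": "exponential", "rate": float(np.exp(-3.22))})
    beta: object = 0.0
    analysis: str = "gb"
    design: str = "fixed"  # fixed | adaptive
    n: int = 1000
    horizon: Optional[float] = 40.0
    age_range: Optional[tuple] = None
    age_cap: Optional[float] = None
    adaptive: Optional[TrialDesignConfig] = None
    thresholds: DecisionThresholds = field(default_factory=lambda: DecisionThresholds(delta=0.975))
    replicates: int = 500
    base_seed: int = 0
    scenario_index: int = 0
    scale: float = 1.0

    @property
    def n_replicates(self) -> int:
        return max(1, int(round(self.replicates * self.scale)))


@dataclass
class ScenarioSummary:
    """Aggregated operating characteristics for one scenario."""

    name: str
    n_replicates: int
    prop_declared_effective: float
    prop_declared_se: float
    mse_of_modes: float
    mse_se: float
    median_diff: float
    median_sq_error: float
    prop_stop_effective: float
    prop_stop_futile: float
    mean_enrollments: float
    mean_enrollments_se: float
    n_failed: int
    records: pd.DataFrame = field(repr=False, default=None)

    @property
    def complete(self) -> bool:
        return self.n_failed == 0


# ---------------------------------------------------------------------------
# canonical study scenarios

#: super-model prior of the illustrative example: hazard values Uniform(0, 0.5)
#: at knots 0, 10, 20, 30, 40 months
SUPER_PRIOR_GENERATOR = {
    "family": "super",
    "knots": (0.0, 10.0, 20.0, 30.0, 40.0),
    "value_range": (0.0, 0.5),
}

#: illustrative-example exponential generator prior: log rate Uniform(-3.72, -2.72)
EXP_PRIOR_GENERATOR = {"family": "exponential", "log_rate_range": (-3.72, -2.72)}

#: point-prior exponential baseline at the illustrative prior midpoint
EXP_MIDPOINT_GENERATOR = {"family": "exponential", "rate": float(np.exp(-3.22))}


def illustrative_scenario(
    generator: str, analysis: str, beta: float, n: int,
    replicates: int = 1000, base_seed: int = 0, scenario_index: int = 0,
) -> ScenarioConfig:
    """Fixed-sample 40-month trial, everyone enrolled at time 0.

    ``generator`` is "exp" (log-rate prior) or "super" (super-model
    prior); declaration threshold Delta = 0.975.
    """
    gen = {"exp": EXP_PRIOR_GENERATOR, "super": SUPER_PRIOR_GENERATOR}[generator]
    return ScenarioConfig(
        name=f"illustrative_{generator}_{analysis}_b{beta}_n{n}",
        generator=gen, beta=beta, analysis=analysis, design="fixed",
        n=n, horizon=40.0, thresholds=DecisionThresholds(delta=0.975),
        replicates=replicates, base_seed=base_seed, scenario_index=scenario_index,
    )


def orvac_fixed_scenario(
    analysis: str, beta: float, replicates: int = 500,
    base_seed: int = 0, scenario_index: int = 0,
) -> ScenarioConfig:
    """Fixed-sample ORVAC-style trial: n=1000, enrollment ages Uniform(6, 12)
    months, follow-up to 36 months of age, declaration threshold 0.97.

    The baseline hazard is the constant exponential rate exp(-3.22)/month
    (illustrative prior midpoint; the redesign's exact curve is shown
    only graphically).
    """
    return ScenarioConfig(
        name=f"orvac_fixed_{analysis}_b{beta}",
        generator=EXP_MIDPOINT_GENERATOR, beta=beta, analysis=analysis,
        design="fixed", n=1000, horizon=None, age_range=(6.0, 12.0), age_cap=36.0,
        thresholds=DecisionThresholds(delta=0.97),
        replicates=replicates, base_seed=base_seed, scenario_index=scenario_index,
    )


def orvac_range_scenario(
    analysis: str, replicates: int = 500, B: int = 100,
    base_seed: int = 0, scenario_index: int = 0, scale: float = 1.0,
) -> ScenarioConfig:
    """Adaptive ORVAC redesign averaged over a range of hazards.

    Super-model prior on the baseline hazard, treatment effect Uniform
    (-0.75, -0.25) per replicate, full ORVAC adaptive design.
    """
    thresholds = DecisionThresholds(delta=0.97, delta_e=0.90, delta_f=0.05, B=B)
    return ScenarioConfig(
        name=f"orvac_range_{analysis}",
        generator=SUPER_PRIOR_GENERATOR, beta=(-0.75, -0.25), analysis=analysis,
        design="adaptive", adaptive=TrialDesignConfig(thresholds=thresholds),
        thresholds=thresholds, horizon=None, age_range=(6.0, 12.0), age_cap=36.0,
        replicates=replicates, base_seed=base_seed, scenario_index=scenario_index,
        scale=scale,
    )


def _draw_generator(gen: dict, beta: float, rng, t_max: float) -> HazardSpec:
    family = gen.get("family", "exponential")
    if family == "exponential":
        if "log_rate_range" in gen:
            lo, hi = gen["log_rate_range"]
            rate = float(np.exp(rng.uniform(lo, hi)))
        else:
            rate = float(gen["rate"])
        return exponential_spec(rate, beta, t_max)
    if family == "weibull":
        return weibull_spec(float(gen["tau1"]), float(gen["tau2"]), beta, t_max)
    if family == "piecewise":
        return piecewise_spec(gen["rates"], gen.get("cutpoints"), beta, t_max)
    if family == "super":
        knots = np.asarray(gen.get("knots", (0.0, 10.0, 20.0, 30.0, 40.0)), dtype=float)
        if "knot_values" in gen:
            values = np.asarray(gen["knot_values"], dtype=float)
            sm = SuperModelSpec(knots, values, fit_super_coefficients(knots, values))
        else:
            sm = sample_super_model_prior(knots, gen.get("value_range", (0.0, 0.5)), rng)
        return super_spec(sm, beta, t_max)
    raise ValueError(f"unknown generator family {family!r}")


def _draw_beta(beta, rng) -> float:
    if np.ndim(beta) == 0:
        return float(beta)
    lo, hi = beta
    return float(rng.uniform(lo, hi))


def _replicate(cfg: ScenarioConfig, j: int) -> dict:
    ss = np.random.SeedSequence([int(cfg.base_seed), int(cfg.scenario_index), int(j)])
    draw_ss, trial_ss = ss.spawn(2)
    rng = np.random.default_rng(draw_ss)
    t_max = float(cfg.horizon) if cfg.horizon else 40.0
    if cfg.age_cap is not None:
        t_max = max(t_max, float(cfg.age_cap))
    beta = _draw_beta(cfg.beta, rng)
    generator = _draw_generator(cfg.generator, beta, rng, t_max)
    analysis = make_analysis(cfg.analysis)

    if cfg.design == "fixed":
        result = run_fixed_trial(
            cfg.n, cfg.horizon, generator, analysis, rng_seed=trial_ss,
            thresholds=cfg.thresholds, age_range=cfg.age_range, age_cap=cfg.age_cap,
        )
    else:
        design = cfg.adaptive or TrialDesignConfig(thresholds=cfg.thresholds)
        if cfg.scale != 1.0:
            th = design.thresholds
            design = replace(
                design,
                thresholds=DecisionThresholds(
                    delta=th.delta, delta_e=th.delta_e, delta_f=th.delta_f,
                    B=max(1, int(round(th.B * cfg.scale))),
                ),
            )
        result = run_adaptive_trial(design, generator, analysis, rng_seed=trial_ss)

    post = result.final_posterior
    return {
        "scenario": cfg.name,
        "replicate": j,
        "beta_true": beta,
        "declared_effective": bool(result.final_declared_effective),
        "posterior_mode": post.mode,
        "prob_beta_lt_0": post.prob_lt_zero,
        "stop_reason": result.stop_reason,
        "n_enrolled": result.n_enrolled,
        "n_interims": result.n_interims,
        "last_expected_effectiveness": result.last_expected_effectiveness,
        "last_futility_expectation": result.last_futility_expectation,
    }


def _bootstrap_se(values: np.ndarray, stat, n_boot: int = 400, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    if n < 2:
        return float("nan")
    idx = rng.integers(0, n, size=(n_boot, n))
    return float(np.std([stat(values[i]) for i in idx], ddof=1))


def run_scenario(cfg: ScenarioConfig, n_jobs: int = 1) -> ScenarioSummary:
    """Simulate all replicates of one scenario and aggregate.

    Replicate failures are recorded (``n_failed``), never fatal; the
    summary flags incomplete scenarios via ``complete``.
    """
    J = cfg.n_replicates
    rows, failed = [], 0
    if n_jobs != 1:
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=n_jobs)(delayed(_safe_replicate)(cfg, j) for j in range(J))
    else:
        outs = [_safe_replicate(cfg, j) for j in range(J)]
    for out in outs:
        if out is None:
            failed += 1
        else:
            rows.append(out)
    if not rows:
        nan = float("nan")
        return ScenarioSummary(
            name=cfg.name, n_replicates=0, prop_declared_effective=nan,
            prop_declared_se=nan, mse_of_modes=nan, mse_se=nan, median_diff=nan,
            median_sq_error=nan, prop_stop_effective=nan, prop_stop_futile=nan,
            mean_enrollments=nan, mean_enrollments_se=nan, n_failed=failed,
            records=pd.DataFrame(),
        )
    df = pd.DataFrame(rows).sort_values("replicate").reset_index(drop=True)

    declared = df["declared_effective"].to_numpy(dtype=float)
    err = df["posterior_mode"].to_numpy() - df["beta_true"].to_numpy()
    enroll = df["n_enrolled"].to_numpy(dtype=float)
    j_eff = declared.size
    p = float(declared.mean())
    return ScenarioSummary(
        name=cfg.name,
        n_replicates=j_eff,
        prop_declared_effective=p,
        prop_declared_se=float(np.sqrt(p * (1 - p) / j_eff)),
        mse_of_modes=float(np.mean(err**2)),
        mse_se=_bootstrap_se(err, lambda e: np.mean(e**2), seed=cfg.base_seed + 1),
        median_diff=float(np.median(err)),
        median_sq_error=float(np.median(err**2)),
        prop_stop_effective=float((df["stop_reason"] == "effective").mean()),
        prop_stop_futile=float((df["stop_reason"] == "futile").mean()),
        mean_enrollments=float(enroll.mean()),
        mean_enrollments_se=_bootstrap_se(enroll, np.mean, seed=cfg.base_seed + 2),
        n_failed=failed,
        records=df,
    )


def _safe_replicate(cfg, j):
    try:
        return _replicate(cfg, j)
    except Exception:  # noqa: BLE001 — a failed replicate must not kill the batch
        return None


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic (non-decreasing) fit."""
    y = y.astype(float).copy()
    w = np.ones_like(y)
    i = 0
    while i < y.size - 1:
        if y[i] > y[i + 1]:
            pooled = (w[i] * y[i] + w[i + 1] * y[i + 1]) / (w[i] + w[i + 1])
            y[i] = y[i + 1] = pooled
            w[i] = w[i + 1] = w[i] + w[i + 1]
            # back-merge
            j = i
            while j > 0 and y[j - 1] > y[j]:
                pooled = (w[j - 1] * y[j - 1] + w[j] * y[j]) / (w[j - 1] + w[j])
                y[j - 1] = y[j] = pooled
                j -= 1
            i = max(j, 0)
        i += 1
    # propagate pooled values
    for i in range(1, y.size):
        y[i] = max(y[i], y[i - 1])
    return y


def power_curve(cfg: ScenarioConfig, n_grid, target: float = 0.8, n_jobs: int = 1) -> pd.DataFrame:
    """Power at each sample size plus a monotone-smoothed estimate.

    Returns a tidy frame (n, power, mc_se, power_smoothed) with an
    attribute ``attrs['smallest_n']`` — the smallest n whose smoothed
    power reaches ``target`` (None if never reached).
    """
    n_grid = sorted(int(n) for n in n_grid)
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    rows = []
    for i, n in enumerate(n_grid):
        sub = replace(cfg, n=n, name=f"{cfg.name}_n{n}", scenario_index=cfg.scenario_index * 1000 + i)
        s = run_scenario(sub, n_jobs=n_jobs)
        rows.append({"n": n, "power": s.prop_declared_effective, "mc_se": s.prop_declared_se})
    df = pd.DataFrame(rows)
    df["power_smoothed"] = _pava(df["power"].to_numpy())
    hit = df[df["power_smoothed"] >= target]
    df.attrs["smallest_n"] = int(hit["n"].iloc[0]) if len(hit) else None
    df.attrs["target"] = target
    return df
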