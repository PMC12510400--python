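"""General Bayesian posterior for the treatment effect via the partial likelihood.

The treatment effect ``beta`` (log hazard ratio) is updated through a
general (Gibbs) posterior

    p(beta | y, x)  proportional to  exp{-w * l(beta, y, x)} * p(beta)

where the loss ``l`` is the negative Cox partial log-likelihood

    l(beta, y, x) = - sum_{i: c_i = 1} [ x_i beta - log sum_{j in R_i} exp(x_j beta) ]

and ``R_i`` is the risk set (subjects with observed time >= t_i) at the
i-th event time.  Because the partial likelihood involves only the
ranking of event times, no baseline hazard is specified at analysis
time; with learning rate ``w = 1`` the posterior is calibrated so that
its mode coincides with the maximum partial-likelihood estimator under
a flat prior.

Ties are handled with the Breslow approximation (tied events share one
risk set and their numerator terms are summed); subjects censored
exactly at an event time remain in that risk set.

The posterior over the scalar ``beta`` is represented either on an
adaptive grid (normalized by the trapezoid rule) or via a Laplace
(Gaussian) approximation at the posterior mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SurvivalSample",
    "GBConfig",
    "PosteriorSummary",
    "partial_log_loss",
    "partial_loss_profile",
    "general_posterior",
    "laplace_posterior",
    "GeneralBayesAnalysis",
]


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored two-arm survival data.

    ``times`` are observed times in months, ``events`` the 0/1 event
    indicators (1 = event, 0 = censored), ``arms`` the 0/1 treatment
    indicators.
    """

    times: np.ndarray
    events: np.ndarray
    arms: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=np.int64)
        x = np.asarray(self.arms, dtype=np.int64)
        if not (t.shape == e.shape == x.shape) or t.ndim != 1:
            raise ValueError("times, events, arms must be equal-length 1-D arrays")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0/1")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("arms must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        object.__setattr__(self, "arms", x)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @staticmethod
    def concat(*samples: "SurvivalSample") -> "SurvivalSample":
        return SurvivalSample(
            np.concatenate([s.times for s in samples]),
            np.concatenate([s.events for s in samples]),
            np.concatenate([s.arms for s in samples]),
        )

    @classmethod
    def from_dataframe(cls, df, col_time="time", col_event="event", col_arm="arm"):
        return cls(df[col_time].to_numpy(), df[col_event].to_numpy(), df[col_arm].to_numpy())


# ---------------------------------------------------------------------------
# partial-likelihood loss


def partial_loss_profile(data: SurvivalSample) -> Callable[[np.ndarray], np.ndarray]:
    """Return a vectorized callable ``loss(beta)`` for fixed data.

    The loss depends on the data only through, per event, the number of
    at-risk subjects in each arm (Breslow risk sets: all subjects with
    observed time >= the event time) and the number of arm-1 events;
    these are precomputed once so repeated evaluation over a beta grid
    is a single vectorized pass.
    """
    if len(data) == 0 or data.n_events == 0:
        def zero(beta):
            return np.zeros_like(np.asarray(beta, dtype=float))
        zero.degenerate = True
        return zero

    t0 = np.sort(data.times[data.arms == 0])
    t1 = np.sort(data.times[data.arms == 1])
    ev = data.events == 1
    et = data.times[ev]
    n0 = t0.size - np.searchsorted(t0, et, side="left")
    n1 = t1.size - np.searchsorted(t1, et, side="left")
    d1 = float(data.arms[ev].sum())
    n0 = n0.astype(float)
    n1 = n1.astype(float)

    def loss(beta):
        b = np.asarray(beta, dtype=float)
        scalar = b.ndim == 0
        b = np.atleast_1d(b)
        denom = np.log(n0[None, :] + np.exp(b)[:, None] * n1[None, :])
        out = -b * d1 + denom.sum(axis=1)
        return out[0] if scalar else out

    loss.degenerate = False
    return loss


def partial_log_loss(data: SurvivalSample, beta: float) -> float:
    """Negative partial log-likelihood at ``beta`` (Breslow ties)."""
    return float(partial_loss_profile(data)(float(beta)))


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass
class PosteriorSummary:
    """Normalized posterior of the treatment effect on a grid.

    ``log_density`` is the unnormalized log posterior on ``grid``;
    ``density`` integrates to 1 by the trapezoid rule.  ``prob_lt_zero``
    is P(beta < 0 | data), the quantity all decision rules consume.
    """

    grid: np.ndarray
    log_density: np.ndarray
    density: np.ndarray = field(repr=False, default=None)
    mode: float = None
    mean: float = None
    sd: float = None
    prob_lt_zero: float = None
    degenerate: bool = False
    boundary_warning: bool = False
    _cdf: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_grid(
        cls,
        grid: np.ndarray,
        log_density: np.ndarray,
        objective: Optional[Callable[[float], float]] = None,
        degenerate: bool = False,
    ) -> "PosteriorSummary":
        grid = np.asarray(grid, dtype=float)
        logd = np.asarray(log_density, dtype=float)
        if not np.all(np.isfinite(logd)):
            if np.all(np.isneginf(logd[~np.isfinite(logd)])):
                pass  # zero-density regions are fine
            else:
                raise ValueError("non-finite log posterior on grid")
        w = np.exp(logd - logd.max())
        z = np.trapezoid(w, grid)
        density = w / z

        i = int(np.argmax(logd))
        boundary = i in (0, grid.size - 1)
        mode = float(grid[i])
        if objective is not None and not boundary:
            res = optimize.minimize_scalar(
                lambda b: -objective(b), bounds=(grid[i - 1], grid[i + 1]), method="bounded",
                options={"xatol": 1e-8},
            )
            if res.success and -res.fun >= logd[i] - 1e-12:
                mode = float(res.x)
        if boundary:
            warnings.warn("posterior mode at grid boundary", RuntimeWarning, stacklevel=2)

        mean = float(np.trapezoid(grid * density, grid))
        var = float(np.trapezoid((grid - mean) ** 2 * density, grid))
        cdf = np.concatenate(
            ([0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(grid)))
        )
        cdf /= cdf[-1]
        p_lt0 = float(np.interp(0.0, grid, cdf, left=0.0, right=1.0))
        return cls(
            grid=grid,
            log_density=logd,
            density=density,
            mode=mode,
            mean=mean,
            sd=float(np.sqrt(var)),
            prob_lt_zero=p_lt0,
            degenerate=degenerate,
            boundary_warning=boundary,
            _cdf=cdf,
        )

    @classmethod
    def from_gaussian(cls, mean: float, sd: float, n_points: int = 401, span: float = 8.0):
        grid = np.linspace(mean - span * sd, mean + span * sd, n_points)
        logd = -0.5 * ((grid - mean) / sd) ** 2
        out = cls.from_grid(grid, logd)
        # exact Gaussian summaries override the grid quadrature
        out.mode = float(mean)
        out.mean = float(mean)
        out.sd = float(sd)
        out.prob_lt_zero = float(stats.norm.cdf(0.0, loc=mean, scale=sd))
        return out

    @classmethod
    def from_draws(cls, draws: np.ndarray, n_points: int = 401):
        draws = np.asarray(draws, dtype=float)
        lo, hi = draws.min(), draws.max()
        pad = 0.1 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, n_points)
        kde = stats.gaussian_kde(draws)
        dens = np.maximum(kde(grid), 1e-300)
        out = cls.from_grid(grid, np.log(dens))
        # empirical summaries from the draws themselves
        out.mean = float(draws.mean())
        out.sd = float(draws.std(ddof=1))
        out.prob_lt_zero = float(np.mean(draws < 0.0))
        return out

    def quantile(self, p) -> float:
        p = np.asarray(p, dtype=float)
        out = np.interp(p, self._cdf, self.grid)
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# general posterior


@dataclass(frozen=True)
class GBConfig:
    """Configuration of the general Bayesian update.

    ``w`` is the learning rate tempering the loss (1 calibrates the
    posterior to the maximum partial-likelihood estimator and is the
    default throughout); the prior on beta is Normal(prior_mean,
    prior_sd**2), vague by default.
    """

    w: float = 1.0
    prior_mean: float = 0.0
    prior_sd: float = 10.0
    grid_lo: float = -3.0
    grid_hi: float = 3.0
    grid_points: int = 601
    method: str = "grid"

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("learning rate w must be positive")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.grid_lo >= self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        if self.grid_points < 50:
            raise ValueError("grid_points must be >= 50")
        if self.method not in ("grid", "laplace"):
            raise ValueError("method must be 'grid' or 'laplace'")

    def log_prior(self, beta):
        b = np.asarray(beta, dtype=float)
        return -0.5 * ((b - self.prior_mean) / self.prior_sd) ** 2


_MAX_WIDENINGS = 8


def _log_posterior(data: SurvivalSample, cfg: GBConfig):
    loss = partial_loss_profile(data)

    def logpost(beta):
        return cfg.log_prior(beta) - cfg.w * loss(beta)

    return logpost, loss.degenerate


def general_posterior(data: SurvivalSample, cfg: GBConfig = GBConfig()) -> PosteriorSummary:
    """Grid representation of exp{-w l(beta)} p(beta), normalized.

    The grid is widened automatically (doubling the half-width) while
    more than 1% of posterior mass sits in the outer 5% of the grid, so
    strong effects never pile up against the boundary.
    """
    logpost, degenerate = _log_posterior(data, cfg)
    lo, hi = cfg.grid_lo, cfg.grid_hi
    for _ in range(_MAX_WIDENINGS):
        grid = np.linspace(lo, hi, cfg.grid_points)
        logd = logpost(grid)
        w = np.exp(logd - logd.max())
        z = np.trapezoid(w, grid)
        edge = int(round(0.05 * cfg.grid_points))
        outer = (
            np.trapezoid(w[:edge], grid[:edge]) + np.trapezoid(w[-edge:], grid[-edge:])
        ) / z
        if outer <= 0.01:
            break
        center = 0.5 * (lo + hi)
        half = hi - center
        lo, hi = center - 2 * half, center + 2 * half
    return PosteriorSummary.from_grid(grid, logd, objective=logpost, degenerate=degenerate)


def laplace_posterior(data: SurvivalSample, cfg: GBConfig = GBConfig()) -> PosteriorSummary:
    """Gaussian approximation at the posterior mode.

    Mean is beta* = argmax log p(beta) - w l(beta); the variance is the
    inverse negative second derivative at beta* (central differences,
    step 1e-4).  Falls back to the grid posterior when the curvature is
    not usable.
    """
    logpost, degenerate = _log_posterior(data, cfg)
    res = optimize.minimize_scalar(
        lambda b: -logpost(b), bounds=(cfg.grid_lo * 4, cfg.grid_hi * 4), method="bounded",
        options={"xatol": 1e-10},
    )
    b_star = float(res.x)
    h = 1e-4
    curv = (logpost(b_star + h) - 2.0 * logpost(b_star) + logpost(b_star - h)) / h**2
    if not np.isfinite(curv) or curv >= 0:
        warnings.warn("Laplace curvature unusable; falling back to grid", RuntimeWarning)
        return general_posterior(data, cfg)
    out = PosteriorSummary.from_gaussian(b_star, float(np.sqrt(-1.0 / curv)))
    out.degenerate = degenerate
    return out


class GeneralBayesAnalysis:
    """Analysis-model adapter: general Bayesian posterior of beta."""

    name = "gb"

    def __init__(self, cfg: GBConfig = GBConfig()):
        self.cfg = cfg

    def posterior(self, data: SurvivalSample) -> PosteriorSummary:
        if self.cfg.method == "laplace" and data.n_events > 0:
            return laplace_posterior(data, self.cfg)
        return general_posterior(data, self.cfg)
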