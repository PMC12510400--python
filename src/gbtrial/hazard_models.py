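"""Proportional-hazards data-generating models.

Every generator is a proportional-hazards model

    h(t | beta, tau) = exp(x * beta) * h0(t | tau)

where ``x`` is the arm indicator (1 = active), ``beta`` the log hazard
ratio, and ``h0`` a baseline hazard from one of four families:

``exponential``
    constant rate ``tau1`` (events/month).
``weibull``
    ``tau1 * tau2 * t**(tau2 - 1)``; reduces to the exponential at
    ``tau2 = 1``.
``piecewise``
    piecewise-constant rates on user-supplied cutpoints.
``super``
    a deliberately flexible cubic-polynomial baseline ("super model"),
    obtained by least-squares fitting a degree-3 polynomial (with
    intercept) to hazard values placed at a handful of knots.  It exists
    to generate a wide variety of plausible data sets — flat, monotone
    and non-monotone hazards — and is never itself the target of
    inference.

Event times are drawn by inverting the cumulative hazard: with
``U ~ Uniform(0,1)``, the solution of ``H(t|x) = -log(U)`` has survivor
function ``exp(-H)``.  Left-truncated draws (needed when imputing
subjects already followed for ``y*`` months without an event) solve
``H(z) = H(y*) - log(U)``, which conditions on survival past ``y*``.
Events past the support horizon ``t_max`` are returned as ``+inf`` and
censored by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FLOOR",
    "HazardSpec",
    "SuperModelSpec",
    "evaluate_hazard",
    "cumulative_hazard",
    "sample_event_time",
    "sample_truncated_event_time",
    "sample_super_model_prior",
    "exponential_spec",
    "weibull_spec",
    "piecewise_spec",
    "super_spec",
]

#: nonnegativity floor for polynomial baselines (events/month)
FLOOR = 1e-6

#: absolute time tolerance for numeric inversion (months)
_ROOT_TOL = 1e-6

_FAMILIES = ("exponential", "weibull", "super", "piecewise")


# ---------------------------------------------------------------------------
# super model


@dataclass(frozen=True)
class SuperModelSpec:
    """Cubic-polynomial baseline hazard fitted to values at knots.

    ``coefficients`` are in increasing-degree order (intercept first);
    the reconstructed baseline is floored at :data:`FLOOR` so it is a
    valid hazard even where the polynomial dips below zero.
    """

    knots: np.ndarray
    knot_values: np.ndarray
    coefficients: np.ndarray
    Q: int = 3

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.knot_values, dtype=float)
        coefs = np.asarray(self.coefficients, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError("need at least 2 knots")
        if knots.size != values.size:
            raise ValueError("knots and knot_values must have equal length")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if knots.size < coefs.size:
            raise ValueError("fewer knots than polynomial coefficients")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "knot_values", values)
        object.__setattr__(self, "coefficients", coefs)

    def polynomial(self, t):
        """Raw (unfloored) polynomial value at ``t``."""
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), self.coefficients)


def fit_super_coefficients(knots, knot_values, degree: int = 3) -> np.ndarray:
    """Least-squares polynomial coefficients (increasing degree, with intercept)."""
    knots = np.asarray(knots, dtype=float)
    knot_values = np.asarray(knot_values, dtype=float)
    if knots.size < degree + 1:
        raise ValueError("fewer knots than polynomial coefficients")
    design = np.vander(knots, degree + 1, increasing=True)
    coefs, *_ = np.linalg.lstsq(design, knot_values, rcond=None)
    return coefs


def sample_super_model_prior(knots, value_range=(0.0, 0.5), rng=None, degree: int = 3) -> SuperModelSpec:
    """Draw one baseline hazard from the super-model prior.

    Hazard values at the knots are drawn i.i.d. Uniform(lo, hi) and a
    degree-``degree`` polynomial (with intercept) is least-squares
    fitted to them.  The induced distribution over the coefficients is
    the prior on the baseline hazard.
    """
    lo, hi = value_range
    if lo < 0 or hi <= lo:
        raise ValueError("value_range must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(rng)
    knots = np.asarray(knots, dtype=float)
    values = rng.uniform(lo, hi, size=knots.size)
    coefs = fit_super_coefficients(knots, values, degree=degree)
    return SuperModelSpec(knots=knots, knot_values=values, coefficients=coefs, Q=degree)


# ---------------------------------------------------------------------------
# baseline representations (value / integral / inverse-integral)


class _ExponentialBaseline:
    def __init__(self, rate: float):
        if rate <= 0:
            raise ValueError(f"exponential rate must be positive, got {rate}")
        self.rate = float(rate)

    def value(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def integral(self, t):
        return self.rate * np.asarray(t, dtype=float)

    def inverse(self, target):
        return np.asarray(target, dtype=float) / self.rate


class _WeibullBaseline:
    def __init__(self, tau1: float, tau2: float):
        if tau1 <= 0 or tau2 <= 0:
            raise ValueError(f"Weibull parameters must be positive, got {(tau1, tau2)}")
        self.tau1 = float(tau1)
        self.tau2 = float(tau2)

    def value(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.tau1 * self.tau2 * np.power(t, self.tau2 - 1.0)
        return out

    def integral(self, t):
        return self.tau1 * np.power(np.asarray(t, dtype=float), self.tau2)

    def inverse(self, target):
        return np.power(np.asarray(target, dtype=float) / self.tau1, 1.0 / self.tau2)


class _PiecewiseBaseline:
    """Piecewise-constant baseline on boundaries [0, c1, ..., cm, t_max]."""

    def __init__(self, rates, cutpoints, t_max):
        rates = np.asarray(rates, dtype=float)
        cuts = np.asarray(cutpoints, dtype=float)
        if np.any(rates <= 0):
            raise ValueError("piecewise rates must be positive")
        bounds = np.concatenate(([0.0], cuts, [t_max]))
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("cutpoints must be strictly increasing within (0, t_max)")
        if rates.size != bounds.size - 1:
            raise ValueError("need one rate per interval")
        self.rates = rates
        self.bounds = bounds
        # cumulative integral at each boundary
        self.cum = np.concatenate(([0.0], np.cumsum(rates * np.diff(bounds))))

    def _segment(self, t):
        return np.clip(np.searchsorted(self.bounds, t, side="right") - 1, 0, self.rates.size - 1)

    def value(self, t):
        return self.rates[self._segment(np.asarray(t, dtype=float))]

    def integral(self, t):
        t = np.asarray(t, dtype=float)
        seg = self._segment(t)
        return self.cum[seg] + self.rates[seg] * (t - self.bounds[seg])

    def inverse(self, target):
        target = np.asarray(target, dtype=float)
        seg = np.clip(np.searchsorted(self.cum, target, side="right") - 1, 0, self.rates.size - 1)
        return self.bounds[seg] + (target - self.cum[seg]) / self.rates[seg]


class _FlooredPolyBaseline:
    """max(FLOOR, polynomial(t)) with exact piecewise-polynomial integration.

    Segment boundaries are the real roots of ``p(t) - FLOOR`` inside
    (0, t_max); on each segment the hazard is either the polynomial or
    the constant floor, so the cumulative hazard is available in closed
    form and inversion reduces to a per-segment monotone root-find.
    """

    def __init__(self, coefficients, t_max, floor=FLOOR):
        self.coefs = np.asarray(coefficients, dtype=float)
        self.floor = float(floor)
        # roots of p(t) - floor, increasing-degree coefficients
        shifted = self.coefs.copy()
        shifted[0] -= self.floor
        roots = np.polynomial.polynomial.polyroots(shifted) if shifted.size > 1 else np.array([])
        interior = np.sort(
            np.unique(
                [r.real for r in np.atleast_1d(roots) if abs(r.imag) < 1e-10 and 0.0 < r.real < t_max]
            )
        )
        self.bounds = np.concatenate(([0.0], interior, [t_max]))
        mids = 0.5 * (self.bounds[:-1] + self.bounds[1:])
        self.above = np.polynomial.polynomial.polyval(mids, self.coefs) >= self.floor
        # antiderivative of the polynomial (increasing degree, constant 0)
        self.anti = np.concatenate(([0.0], self.coefs / np.arange(1, self.coefs.size + 1)))
        # cumulative integral of the floored hazard at each boundary
        widths = np.diff(self.bounds)
        poly_parts = np.diff(np.polynomial.polynomial.polyval(self.bounds, self.anti))
        seg_int = np.where(self.above, poly_parts, self.floor * widths)
        self.cum = np.concatenate(([0.0], np.cumsum(seg_int)))

    def _segment(self, t):
        return np.clip(np.searchsorted(self.bounds, t, side="right") - 1, 0, self.above.size - 1)

    def value(self, t):
        return np.maximum(self.floor, np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), self.coefs))

    def integral(self, t):
        t = np.asarray(t, dtype=float)
        seg = self._segment(t)
        lo = self.bounds[seg]
        poly_part = np.polynomial.polynomial.polyval(t, self.anti) - np.polynomial.polynomial.polyval(
            lo, self.anti
        )
        part = np.where(self.above[seg], poly_part, self.floor * (t - lo))
        return self.cum[seg] + part

    def inverse(self, target):
        target = np.asarray(target, dtype=float)
        seg = np.clip(np.searchsorted(self.cum, target, side="right") - 1, 0, self.above.size - 1)
        lo = self.bounds[seg].copy()
        hi = self.bounds[seg + 1].copy()
        # floor segments are linear in t
        flat = ~self.above[seg]
        out = np.empty_like(target)
        out[flat] = lo[flat] + (target[flat] - self.cum[seg][flat]) / self.floor
        # polynomial segments: bisection on the monotone cumulative integral
        poly = ~flat
        if np.any(poly):
            plo, phi = lo[poly], hi[poly]
            tgt = target[poly]
            for _ in range(80):
                if np.max(phi - plo) < _ROOT_TOL:
                    break
                mid = 0.5 * (plo + phi)
                too_low = self.integral(mid) < tgt
                plo = np.where(too_low, mid, plo)
                phi = np.where(too_low, phi, mid)
            out[poly] = 0.5 * (plo + phi)
        return out


# ---------------------------------------------------------------------------
# hazard spec


@dataclass(frozen=True)
class HazardSpec:
    """One proportional-hazards data-generating model.

    Parameters
    ----------
    family : {"exponential", "weibull", "super", "piecewise"}
    beta : float
        Log hazard ratio of the active arm (x=1) vs placebo (x=0).
    params : tuple | SuperModelSpec | dict
        Family-specific nuisance parameters: ``(tau1,)`` for the
        exponential, ``(tau1, tau2)`` for the Weibull, a
        :class:`SuperModelSpec` for the super model, and
        ``{"rates": [...], "cutpoints": [...]}`` for the piecewise
        exponential (cutpoints default to 6 equal-width pieces).
    t_max : float
        Support horizon in months for numeric inversion; events past it
        are reported as ``+inf``.
    """

    family: str
    beta: float
    params: object
    t_max: float = 40.0
    _baseline: object = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        object.__setattr__(self, "_baseline", self._build_baseline())

    def _build_baseline(self):
        if self.family == "exponential":
            (tau1,) = np.atleast_1d(self.params)
            return _ExponentialBaseline(tau1)
        if self.family == "weibull":
            tau1, tau2 = np.atleast_1d(self.params)
            return _WeibullBaseline(tau1, tau2)
        if self.family == "super":
            sm = self.params
            if not isinstance(sm, SuperModelSpec):
                raise ValueError("super family requires a SuperModelSpec in params")
            return _FlooredPolyBaseline(sm.coefficients, self.t_max)
        # piecewise
        p = self.params
        rates = np.asarray(p["rates"], dtype=float)
        cuts = p.get("cutpoints")
        if cuts is None:
            cuts = np.linspace(0.0, self.t_max, rates.size + 1)[1:-1]
        return _PiecewiseBaseline(rates, cuts, self.t_max)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"family": self.family, "beta": float(self.beta), "t_max": float(self.t_max)}
        if self.family == "super":
            sm: SuperModelSpec = self.params
            d["knots"] = sm.knots.tolist()
            d["knot_values"] = sm.knot_values.tolist()
        elif self.family == "piecewise":
            d["rates"] = np.asarray(self.params["rates"], dtype=float).tolist()
            cuts = self.params.get("cutpoints")
            if cuts is not None:
                d["cutpoints"] = np.asarray(cuts, dtype=float).tolist()
        else:
            d["params"] = np.atleast_1d(self.params).astype(float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HazardSpec":
        family = d["family"]
        beta = float(d.get("beta", 0.0))
        t_max = float(d.get("t_max", 40.0))
        if family == "super":
            coefs = fit_super_coefficients(d["knots"], d["knot_values"])
            sm = SuperModelSpec(
                knots=np.asarray(d["knots"], float),
                knot_values=np.asarray(d["knot_values"], float),
                coefficients=coefs,
            )
            return cls(family, beta, sm, t_max)
        if family == "piecewise":
            params = {"rates": d["rates"], "cutpoints": d.get("cutpoints")}
            return cls(family, beta, params, t_max)
        return cls(family, beta, tuple(d["params"]), t_max)


def exponential_spec(rate: float, beta: float = 0.0, t_max: float = 40.0) -> HazardSpec:
    return HazardSpec("exponential", beta, (rate,), t_max)


def weibull_spec(tau1: float, tau2: float, beta: float = 0.0, t_max: float = 40.0) -> HazardSpec:
    return HazardSpec("weibull", beta, (tau1, tau2), t_max)


def piecewise_spec(
    rates: Sequence[float],
    cutpoints: Optional[Sequence[float]] = None,
    beta: float = 0.0,
    t_max: float = 40.0,
) -> HazardSpec:
    return HazardSpec("piecewise", beta, {"rates": np.asarray(rates, float), "cutpoints": cutpoints}, t_max)


def super_spec(model: SuperModelSpec, beta: float = 0.0, t_max: float = 40.0) -> HazardSpec:
    return HazardSpec("super", beta, model, t_max)


# ---------------------------------------------------------------------------
# operations


def _check_time(spec: HazardSpec, t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.t_max):
        raise ValueError(f"time outside [0, {spec.t_max}]")
    return t


def _maybe_scalar(out, *inputs):
    if all(np.ndim(i) == 0 for i in inputs):
        return float(out)
    return out


def evaluate_hazard(spec: HazardSpec, t, x):
    """Hazard rate h(t|x) = exp(x*beta) * h0(t), events/month."""
    tt = _check_time(spec, t)
    out = np.exp(np.asarray(x) * spec.beta) * spec._baseline.value(tt)
    return _maybe_scalar(out, t, x)


def cumulative_hazard(spec: HazardSpec, t, x):
    """Integrated hazard H(t|x) = exp(x*beta) * int_0^t h0(u) du."""
    tt = _check_time(spec, t)
    out = np.exp(np.asarray(x) * spec.beta) * spec._baseline.integral(tt)
    return _maybe_scalar(out, t, x)


def _check_u(u):
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("uniform draw must lie strictly in (0, 1)")
    return u


def sample_event_time(spec: HazardSpec, x, u):
    """Event time solving H(t|x) = -log(u); +inf if beyond t_max."""
    uu = _check_u(u)
    target0 = -np.log(uu) * np.exp(-np.asarray(x) * spec.beta)  # baseline-scale target
    h_max = spec._baseline.integral(np.asarray(spec.t_max, dtype=float))
    beyond = target0 > h_max
    t = np.where(beyond, np.inf, spec._baseline.inverse(np.minimum(target0, h_max)))
    return _maybe_scalar(t, x, u)


def sample_truncated_event_time(spec: HazardSpec, x, y_star, u):
    """Left-truncated event time z > y_star with S(z|x)/S(y_star|x) = u.

    Solves H0(z) = H0(y_star) - exp(-x*beta) * log(u); returns +inf when
    the conditional event falls beyond ``t_max``.
    """
    uu = _check_u(u)
    ys = _check_time(spec, y_star)
    if np.any(ys >= spec.t_max):
        raise ValueError("y_star must be < t_max")
    target0 = spec._baseline.integral(ys) - np.log(uu) * np.exp(-np.asarray(x) * spec.beta)
    h_max = spec._baseline.integral(np.asarray(spec.t_max, dtype=float))
    beyond = target0 > h_max
    z = np.where(beyond, np.inf, spec._baseline.inverse(np.minimum(target0, h_max)))
    z = np.maximum(z, np.nextafter(ys, np.inf))  # strict z > y_star under rounding
    return _maybe_scalar(z, x, y_star, u)
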