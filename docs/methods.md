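# Methods

## The inference problem

A two-arm trial observes right-censored times-to-event `yᵢ = (tᵢ, cᵢ)` with
arm indicators `xᵢ ∈ {0,1}` under proportional hazards
`h(t|x) = exp(xβ)·h0(t)`. The estimand is the log hazard ratio `β`. The
package's central posterior is the general (Gibbs) Bayesian update

    p(β|y,x) ∝ exp{−w·l(β,y,x)}·p(β)

with `l` the negative Cox partial log-likelihood. Since `l` depends on the
data only through event-time rankings and risk sets, the baseline hazard
drops out of the analysis entirely; `w` tempers the loss and is fixed at 1,
which calibrates the posterior mode to the maximum partial-likelihood
estimator (the `GBConfig.w` field exists for sensitivity analyses only).
The prior on `β` is Normal(0, 10²) by default — effectively flat over any
plausible hazard ratio — and is always config-visible, because the vague
priors used in published analyses of this design are rarely stated exactly.

Ties are handled with the Breslow approximation: tied events share one risk
set and their numerator terms are summed. Continuous simulation makes ties
measure-zero, but imported tables may round times. Subjects censored
exactly at an event time remain in that risk set (events-before-censoring
at equal times).

### Posterior representations

* **Grid** (default): `log p(β) − w·l(β)` on 601 points over [−3, 3],
  normalized by the trapezoid rule after a log-sum-exp shift. If more than
  1% of posterior mass falls in the outer 5% of the grid, the half-width
  doubles (up to 8 times), so strong effects never clip. The mode is
  refined inside its bracketing cell by bounded scalar optimization;
  `P(β<0)` integrates the normalized density left of zero.
* **Laplace**: Gaussian at `β* = argmax`, variance the inverse negative
  second difference (step 1e-4). The partial log-likelihood is concave in
  `β`, so the objective is unimodal; non-usable curvature falls back to the
  grid with a warning. Used when thousands of refits are needed.

### Parametric comparators

Exponential, Weibull, piecewise-exponential (fixed cutpoints, 6 equal-width
pieces by default) and the polynomial "super" model are fitted by standard
Bayesian inference on the censored-data likelihood
`Σ cᵢ log h(tᵢ) − H(tᵢ)`. The sampler is a blocked adaptive random-walk
Metropolis on (β, log-nuisances): β updates alone, the nuisances update
jointly with a proposal whose shape adapts to their running covariance
during burn-in (the Weibull rate and shape are strongly correlated).
Defaults: 4000 iterations, 1000 burn-in, scaling adapted toward 0.35
acceptance, seed-controlled; a split-chain R̂ > 1.1 attaches a non-fatal
warning. Super-model knot values stay on the natural scale under their
Uniform(0, 0.5) prior.

Default priors (all config-visible): `β ~ N(0,10²)`;
`log τ₁ ~ N(−3.22, 1)` — centered on the midpoint of the illustrative
log-rate prior U(−3.72, −2.72); `log τ₂ ~ N(0, 0.5²)`; piecewise log-rates
i.i.d. `N(−3.22, 1)`.

Two deterministic shortcuts serve the simulation loops, where a posterior
of `β` alone is refitted thousands of times:

* the **exponential** model's likelihood depends on the data only through
  event counts and total time per arm, so its marginal `β` posterior is
  computed exactly on a 2-D (β, log-rate) quadrature grid;
* **Weibull** and **piecewise** analyses use a Laplace approximation (MAP
  by warm-started BFGS, marginal `β` standard deviation from the inverse
  Hessian).

These agree with the Metropolis fits (tested) and remove MCMC noise from
declaration thresholds. The Metropolis route remains the source of
full-parameter θ draws for predictive imputation.

A reversible-jump scheme that would also infer the number of
piecewise-exponential pieces is deliberately out of scope; the
fixed-cutpoint model stands in as the semiparametric comparator.

## Data generation

Event times are drawn by inverting the cumulative hazard:
`t = H⁻¹(−log U)`. Closed forms cover the exponential and Weibull;
piecewise-exponential inverts segment-wise; the super model's floored
polynomial uses exact piecewise-polynomial integration (segment boundaries
at the roots of `p(t) − ε`) with vectorized bisection to 1e-6 months inside
a segment. Events beyond the support horizon `t_max` return `+inf` and are
censored by the caller — `t_max` defaults to the trial horizon (40 months
for the illustrative design; the 36-months-of-age cap governs ORVAC-style
follow-up).

### The super model

`s0(t|ψ)` is a degree-3 polynomial fitted by least squares to hazard
values placed at knots (default 0, 10, 20, 30, 40 months); its prior is
induced by drawing the knot values i.i.d. Uniform(0, 0.5) events/month.
Two choices deserve note:

* **Intercept.** A pure `Σ_{q=1..3} ψ_q t^q` basis forces `s0(0)=0`, yet the
  prior places mass on the hazard value at the knot `t=0`. The package
  therefore includes an intercept (4 coefficients) so the stated prior at
  `t=0` is honored; with 5 knots and 4 coefficients the fit is a
  least-squares projection, not an interpolation.
* **Nonnegativity.** Cubics can dip below zero between knots; the baseline
  is floored at ε = 1e-6 events/month and the floored function is
  integrated exactly.

Inside MCMC (where the super model is refitted at every interim), the
cumulative hazard of the floored polynomial is instead integrated by the
trapezoid rule on a fixed 1601-point grid — this differs from the exact
segment integral by ~1e-4 nats on realistic data (tested) and is an order
of magnitude faster. Data generation always uses the exact path.

The super-model prior emulates a *range of plausible baseline-hazard
shapes* — flat, monotone, non-monotone — with hazards up to 0.5
events/month. It does not emulate covariate effects, non-proportional
hazards, dropout, or seasonality; conclusions from passing tests are
accordingly about robustness to baseline-hazard shape, not to those
features.

## Trial simulation

Calendar time advances in 1-month steps. ORVAC defaults: 50 participants
enroll at the start of each 3-month block (uniform within-block spreading
was considered and rejected as the default because the published design
text specifies only the per-block rate), ages Uniform(6, 12) months,
Bernoulli(½) allocation, maximum 1000. Latent event times are drawn once at
enrollment and never change; censoring status is recomputed from the trial
clock. An interim runs at the first month at which cumulative enrollment
reaches 250, then every additional 50.

At an interim the population splits into *exited* subjects (event observed,
or follow-up exhausted) and *pending* subjects, administratively censored
at elapsed time `y*`. The imputation model (the analysis model's own family
for parametric analyses; the super model, updated by standard Bayes with
free knot values, for the general Bayesian analysis — the choice is
configurable because no published convention exists) is refitted to the
interim data, and the two rules are evaluated with B Monte-Carlo
repetitions, each under a fresh θ draw:

* **Expected effectiveness**: impute left-truncated completions `z > y*`
  for pending subjects, refit the analysis posterior, record
  `I{P(β<0) > Δ}`; stop when the mean exceeds Δe.
* **Futility**: additionally simulate arms and outcomes for everyone not
  yet enrolled up to the maximum (continuing the enrollment schedule from
  the next block, ages redrawn); stop when the mean falls below Δf.

Imputed and simulated outcomes are re-censored at the 36-months-of-age cap
(and the trial horizon where one exists). Effectiveness is checked before
futility; both are logged at every interim. Thresholds default to Δ=0.97,
Δe=0.90, Δf=0.05. B defaults to 100 — no published value exists, and the
Monte-Carlo error of an indicator mean at B=100 (≤0.05) is small against
the 0.90/0.05 thresholds. On stopping, all enrolled participants are
followed to the end of their window before the final declaration
`P(β<0|y) > Δ` (analysis at the stop date is a config flag; the published
description is ambiguous on this point).

Two behaviors worth knowing:

* An interim taken with almost no follow-up (possible only in aggressively
  scaled-down designs) has a prior-driven imputation posterior, and the
  futility rule can then fire essentially at random. The ORVAC schedule
  (first look at 250 enrollments, ~month 12) avoids this regime.
* In the parametric censored-data likelihood, all-censored data still
  carry information about β through the survival terms; only with zero
  events *and* zero exposure is the posterior the prior. The degenerate
  zero-event adapters return the prior (flagged) — this matters only for
  pathological configurations such as a zero-length horizon.

## Scenario batches and seeds

`run_scenario` simulates J independent trials; per-replicate streams derive
from `SeedSequence(base_seed, scenario_index, replicate)`, so adding
scenarios or reordering execution (including joblib workers) never perturbs
existing replicates. Generator priors (log-rate interval, super-model knot
prior, β intervals) are redrawn per replicate. Summaries carry Monte-Carlo
standard errors: binomial for proportions, bootstrap (400 resamples,
seeded) for means and MSEs. Power curves add a pool-adjacent-violators
monotone smoother before locating the smallest n reaching the target.

## Problem sizes used in the checked runs

The acceptance script runs the five fixed-sample quantities at their study
sizes (J=1000 for the illustrative Type I error and power, J=500 for the
ORVAC-style cells) — about a minute of CPU. The adaptive-redesign estimands
are exercised in the test suite at J=100 replicates with B=50, the
package's desk-scale setting for a simulation whose full-size version
(J=500, B≥100) is a batch job; tolerances there are widened accordingly.

## Known limitations

* The exact baseline hazards behind the published redesign's point-prior
  generators exist only as figures; the package's stand-ins (rate
  exp(−3.22)/month exponential; Weibull with shape 1.5, chosen so the
  misspecified exponential analysis attenuates the effect, matching the
  described direction; mid-range super-model knot values) are labeled
  approximations, and quantities tied to those exact curves (e.g. the
  printed MSE level of the exponential-data cells) reproduce only up to
  the event-count those rates imply.
* The super model's five knot values are weakly identified by design
  (over-parameterized generator); their chains mix slowly (R̂ up to ~1.6)
  even though `β` and the implied hazard mix well. This is acceptable for
  predictive imputation and flagged, not hidden, by the R̂ warning.
* Single binary covariate (arm) only; no non-proportional hazards,
  response-adaptive randomization, multi-arm dropping, or dropout
  processes.
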