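# Methods

## Problem

A model fitted by maximum likelihood gives a point estimate
`theta_hat = argmin l(theta)`, where `l` is the negative log-likelihood
(times two, so that likelihood-ratio asymptotics apply directly). The
profile likelihood of one parameter,

    l_PL(theta_i) = min over theta_{j != i} of l(theta),

defines the likelihood-based confidence interval at level `alpha` as

    CI = { theta_i : l_PL(theta_i) <= loss_crit },
    loss_crit = l(theta_hat) + delta_alpha,

with `delta_alpha` the `alpha` quantile of a chi-square distribution. A
parameter is *practically identifiable* when this interval is finite. The
classical way to find the interval — tracing `l_PL` stepwise, re-optimizing
all nuisance parameters at every step — costs thousands of loss evaluations
and has no natural stopping rule in the non-identifiable case.

## The endpoint search

This package computes each endpoint directly as a constrained optimum:

    lower endpoint:  minimize  +theta_i  subject to  l(theta) - loss_crit <= 0
    upper endpoint:  minimize  -theta_i  subject to  l(theta) - loss_crit <= 0

The first-order (KKT) conditions of these problems are exactly the equations
satisfied by a profile-threshold crossing, provided the directional
derivative of `l` along `theta_i` does not vanish at the crossing. The
solver never needs the intermediate iterates to lie on the profile path,
which is where the savings in loss-function calls come from.

The constraint is folded into the objective with an augmented Lagrangian for
a single inequality constraint `g(theta) = l(theta) - loss_crit`:

    psi(g; mu, rho) = mu*g + (rho/2)*g^2   if g >= -mu/rho,
                      -mu^2/(2*rho)        otherwise,

and each outer iteration minimizes `sign*theta_i + psi(g; mu, rho)` over the
parameter box with a derivative-free local solver, then updates
`mu <- max(0, mu + rho*g)` and multiplies `rho` by 10 whenever the constraint
violation failed to shrink by a factor of 4 (start `rho = 1`, cap `1e12`).
This schedule is standard practice for augmented-Lagrangian methods with
safeguarded penalty growth. Because `psi` is inert while the iterate is
comfortably feasible, a search on a flat profile marches straight to the
scan bound at almost no cost — the behaviour that makes non-identifiable
parameters cheap rather than expensive.

The inner solver is Nelder–Mead with box bounds (scipy), warm-started from
the previous outer iterate. Any scipy `minimize` method name, or a callable
with the signature `(fun, x0, bounds=..., maxfev=...)`, can be substituted;
the method itself needs no gradients. One practical detail: scipy seeds the
Nelder–Mead simplex with a 5% relative perturbation of the start point,
which degenerates when a warm-started coordinate is near zero, so both the
endpoint search and the profile oracle build an explicit initial simplex
with an absolute step floor (`_optim.initial_simplex`).

## Scan bounds and termination

Non-identifiability cannot be certified by searching all of R, so the user
declares *scan bounds* `(lo, hi)` for `theta_i` — biologically or
numerically plausible values — and the search answers the question
"identifiable **within these bounds**?". The target parameter's box is the
intersection of the user's parameter bounds with the scan bounds, so the
inner solver can never step outside them. Exactly one of three statuses is
returned:

* `BORDER_FOUND_BY_SCAN_TOL` — the outer loop's endpoint estimate moved by
  less than `scan_tol` between successive iterations while the constraint is
  active to within `loss_tol` (`|l(theta*) - loss_crit| <= loss_tol`). The
  endpoint and its full parameter vector are reported in natural scale.
* `SCAN_BOUNDS_REACHED` — a feasible point (loss below `loss_crit - loss_tol`)
  was observed with `theta_i` within `scan_tol` of, or beyond, the active
  scan bound. Such a point is a *certificate*: the confidence region
  provably extends to the bound, independent of anything else the optimizer
  did. No endpoint is reported.
* `MAX_ITER_STOP` — the evaluation budget (`max_evals`, default 1e5) or the
  outer-iteration cap (60) ran out without either certificate.

An interval is `identifiable_within_bounds` iff both directions returned
`BORDER_FOUND_BY_SCAN_TOL`. A degenerate crossing with vanishing directional
derivative (a stationary point of `l` exactly at the threshold) is not
special-cased: the estimate stalls with an inactive constraint, a warning is
logged, and tightening the tolerances is the documented remedy — in practice
exact degeneracy does not occur in noisy-data problems.

## Parameter scales

Each parameter may be searched in `direct`, `log` (base 10), or `logit`
space. All three maps are strictly increasing, so endpoint ordering is
preserved; `scan_bounds`, `theta_bounds` and `scan_tol` are interpreted in
the search scale (one tolerance meaning regardless of parameter magnitude),
and all reported endpoints are mapped back to natural scale. Log scale is
the right choice for positive parameters spanning decades; logit for
fractions in (0, 1).

## Tunable parameters

| name | default | meaning |
|---|---|---|
| `alpha`, `df` | —, 1 | chi-square quantile defining `loss_crit`; `df = 1` is the pointwise single-parameter convention, which is this package's deliberate default (some workflows use `df = m` for simultaneous coverage — pass it explicitly) |
| `loss_crit` | — | direct threshold; overrides `alpha`/`df` when both are given |
| `scan_bounds` | `(1e-9, 1e9)` natural scale | feasible range of the scanned parameter; the default suits positive biological parameters — sign-indefinite parameters need explicit bounds |
| `theta_bounds` | `(-1e9, 1e9)` search scale | box for all parameters |
| `scan_tol` | `1e-3` search scale | absolute endpoint tolerance |
| `loss_tol` | `1e-3 * (loss_crit - l_min)` | tolerance on constraint activity at the endpoint |
| `max_evals` | `100000` | loss-call budget per endpoint |
| `local_alg` | `nelder-mead` | inner solver |

Loss evaluations are counted exactly (one per call, including failures);
`loss_calls` in every result is the hardware-independent cost metric.
Exceptions and non-finite values from the user's loss become a `+inf`
sentinel rather than propagating, so the search can step through regions
where a stiff ODE solver fails.

## The profile oracle

`compute_profile` implements the classical stepwise profiling — fix
`theta_i` on a grid, re-optimize the nuisance parameters at each point,
warm-starting from the neighbouring argmin and sweeping outward from the
start value in both directions. `crossing_from_profile` linearly
interpolates the outermost threshold crossing on each side. Inside this
package the oracle exists to *validate* the endpoint search (the two routes
agree on every bundled fixture to within `max(scan_tol, grid spacing)`) and
to draw profile plots; it is deliberately the expensive method the endpoint
search replaces.

## Synthetic data

The generator produces Gaussian-noise observations of closed-form
observables with known noise SD, matching the weighted-sum-of-squared-
residuals likelihood `l = sum ((obs - pred)/sigma)^2` exactly:

* a straight line (`slope 2, intercept 1, sigma 0.5, 10 time points on
  [0, 10]` in the coverage study) — the linear-Gaussian case where the 95%
  profile interval for the slope has exactly nominal coverage, so the
  observed coverage over 200 replicates tests the whole pipeline against a
  known truth;
* a biexponential decay `a1*exp(-k1 t) + a2*exp(-k2 t)` — with well-separated
  rates all four parameters are identifiable; with `k1 == k2` the data
  constrain only `a1 + a2`, giving an exactly flat amplitude profile that
  exercises the scan-bound certificate on a model-like loss.

What these fixtures do **not** emulate: ODE integration error interacting
with the optimizer, non-Gaussian or estimated error models, and
high-dimensional correlated parameter spaces. Passing tests therefore
demonstrate correctness of the endpoint search on exact likelihood surfaces
of the right qualitative shapes, not robustness to solver noise.

Datasets regenerate bit-identically from their seed; problem sizes
throughout (2–4 parameters, grids of 41–121 points, 200 coverage
replicates) were chosen so the full validation runs in seconds on a laptop
while keeping Monte-Carlo error small relative to the tested tolerances.

## Known limitations

* Local search: with a multimodal loss the first certified endpoint wins;
  no global stage is attempted. Start from the MLE.
* The `SCAN_BOUNDS_REACHED` certificate is one-sided evidence — it proves
  non-identifiability within the bounds but does not distinguish "flat
  forever" from "crosses just outside the bounds".
* Simultaneous confidence regions and prediction bands are out of scope;
  intervals are per-parameter.
* `df = 1` coverage is pointwise per parameter, not familywise.
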