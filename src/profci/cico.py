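"""Confidence-interval endpoints by constrained optimization (CICO).

A profile-likelihood confidence interval endpoint for parameter ``i`` is
the extreme value of ``theta_i`` inside the confidence region
``{theta : l(theta) <= loss_crit}``.  Instead of tracing the profile
``l_PL(theta_i)`` step by step, the endpoint is obtained directly as the
solution of a constrained optimization problem

    minimize  +theta_i   (lower endpoint)  or  -theta_i  (upper endpoint)
    subject to  l(theta) - loss_crit <= 0,

solved by an outer augmented-Lagrangian loop around a derivative-free
local optimizer.  Intermediate iterates are free to leave the profile
path, which is what makes the search cheap in loss-function calls.

Termination is formalized through *scan bounds*: a pre-declared feasible
range for ``theta_i``.  The search either converges to an endpoint
inside the bounds (``BORDER_FOUND_BY_SCAN_TOL``) or certifies a feasible
point at/beyond a bound, proving the interval leaves the scanned region
(``SCAN_BOUNDS_REACHED`` — the parameter is practically non-identifiable
within the bounds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize

from ._optim import initial_simplex
from .errors import DomainError, InfeasibleStartError
from .objective import LossEvaluator, ThresholdSpec, make_threshold
from .transforms import from_search_scale, to_search_scale, validate_scale, vector_from_search

logger = logging.getLogger(__name__)

__all__ = [
    "BORDER_FOUND_BY_SCAN_TOL",
    "SCAN_BOUNDS_REACHED",
    "MAX_ITER_STOP",
    "CONTINUE",
    "EndpointRequest",
    "EndpointResult",
    "IntervalResult",
    "augmented_objective",
    "certify_termination",
    "find_endpoint",
    "find_interval",
]

BORDER_FOUND_BY_SCAN_TOL = "BORDER_FOUND_BY_SCAN_TOL"
SCAN_BOUNDS_REACHED = "SCAN_BOUNDS_REACHED"
MAX_ITER_STOP = "MAX_ITER_STOP"
CONTINUE = "CONTINUE"

#: default scan bounds in natural scale: wide enough for typical
#: biological rate/concentration parameters spanning many decades.
DEFAULT_SCAN_BOUNDS = (1e-9, 1e9)
#: default box for nuisance parameters, in search scale.
DEFAULT_THETA_BOUND = (-1e9, 1e9)

_RHO_INIT = 1.0
_RHO_GROWTH = 10.0
_RHO_MAX = 1e12
_MAX_OUTER = 60


@dataclass
class EndpointRequest:
    """One endpoint-search problem.

    All geometric quantities (``scan_bounds``, ``theta_bounds``,
    ``scan_tol``) live in the *search scale* defined per parameter by
    ``scales``; ``theta_init`` is in the natural scale.
    """

    evaluator: LossEvaluator
    theta_init: np.ndarray
    index: int
    direction: str  # "lower" | "upper"
    threshold: ThresholdSpec
    scan_bounds: Tuple[float, float]
    theta_bounds: List[Tuple[float, float]]
    scales: List[str]
    scan_tol: float = 1e-3
    loss_tol: float = 1e-3
    max_evals: int = 100_000
    local_alg: Union[str, Callable] = "nelder-mead"

    def __post_init__(self):
        self.theta_init = np.asarray(self.theta_init, dtype=float)
        m = self.theta_init.size
        if not 0 <= self.index < m:
            raise DomainError(f"index {self.index} outside 0..{m - 1}")
        if self.direction not in ("lower", "upper"):
            raise DomainError(f"direction must be 'lower' or 'upper', got {self.direction!r}")
        for s in self.scales:
            validate_scale(s)
        if len(self.scales) != m or len(self.theta_bounds) != m:
            raise DomainError("scales and theta_bounds must have one entry per parameter")
        if not (self.scan_tol > 0 and self.loss_tol > 0 and self.max_evals >= 1):
            raise DomainError("scan_tol, loss_tol must be > 0 and max_evals >= 1")
        lo, hi = self.scan_bounds
        xi = to_search_scale(self.theta_init[self.index], self.scales[self.index], self.index)
        if not (lo < xi < hi):
            raise DomainError(
                f"theta_init[{self.index}] = {xi} (search scale) must lie strictly "
                f"inside scan_bounds ({lo}, {hi})"
            )

    @property
    def sign(self) -> float:
        """+1 when minimizing theta_i (lower endpoint), -1 when maximizing."""
        return 1.0 if self.direction == "lower" else -1.0

    @property
    def active_scan_bound(self) -> float:
        """The scan bound the search moves toward."""
        return self.scan_bounds[0] if self.direction == "lower" else self.scan_bounds[1]


@dataclass
class EndpointResult:
    """Outcome of one endpoint search.

    ``endpoint``/``argument`` are in the natural scale and present only
    for ``BORDER_FOUND_BY_SCAN_TOL``.  ``trace`` records one row per
    outer augmented-Lagrangian iteration:
    (iteration, endpoint estimate in search scale, loss, mu, rho).
    """

    endpoint: Optional[float]
    status: str
    loss_calls: int
    argument: Optional[np.ndarray] = None
    trace: List[Tuple[int, float, float, float, float]] = field(default_factory=list)
    direction: str = ""
    index: int = 0

    def to_dict(self) -> dict:
        return {
            "endpoint": None if self.endpoint is None else float(self.endpoint),
            "status": self.status,
            "loss_calls": int(self.loss_calls),
        }


@dataclass
class IntervalResult:
    """Lower and upper endpoint searches for one parameter."""

    lower: EndpointResult
    upper: EndpointResult
    index: int = 0
    threshold: Optional[ThresholdSpec] = None
    scan_bounds: Optional[Tuple[float, float]] = None
    scale: str = "direct"

    @property
    def identifiable_within_bounds(self) -> bool:
        return (
            self.lower.status == BORDER_FOUND_BY_SCAN_TOL
            and self.upper.status == BORDER_FOUND_BY_SCAN_TOL
        )

    @property
    def loss_calls(self) -> int:
        return self.lower.loss_calls + self.upper.loss_calls

    def to_report(self) -> dict:
        return {
            "parameter": self.index + 1,  # 1-based in reports
            "lower": self.lower.to_dict(),
            "upper": self.upper.to_dict(),
            "identifiable_within_bounds": self.identifiable_within_bounds,
            "loss_crit": None if self.threshold is None else float(self.threshold.loss_crit),
            "scan_bounds": None if self.scan_bounds is None else list(self.scan_bounds),
            "scale": self.scale,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_report(), **kwargs)


def _psi(g: float, mu: float, rho: float) -> float:
    """Augmented-Lagrangian term for the inequality constraint g <= 0.

    The standard Rockafellar form: quadratic in the violated/near-active
    region, constant once the constraint is comfortably satisfied.
    ``rho == 0`` degenerates to the plain Lagrangian term ``mu * g``.
    """
    if not np.isfinite(g):
        return np.inf
    if rho <= 0.0:
        return mu * g
    if g >= -mu / rho:
        return mu * g + 0.5 * rho * g * g
    return -0.5 * mu * mu / rho


def augmented_objective(theta, mu: float, rho: float, request: EndpointRequest) -> float:
    """Augmented Lagrangian of the endpoint problem at a search-scale point.

    ``f(theta) + psi(l(theta) - loss_crit, mu, rho)`` with
    ``f = sign * theta_i``.  Loss failures arrive as the ``+inf``
    sentinel and dominate the sum.
    """
    x = np.asarray(theta, dtype=float)
    natural = vector_from_search(x, request.scales)
    g = request.evaluator(natural) - request.threshold.loss_crit
    return request.sign * x[request.index] + _psi(g, mu, rho)


def certify_termination(
    best_feasible: Optional[Tuple[np.ndarray, float]],
    scan_bound: float,
    request: EndpointRequest,
    endpoint_estimate: Optional[float] = None,
    previous_estimate: Optional[float] = None,
    endpoint_loss: Optional[float] = None,
) -> str:
    """Decide whether an endpoint search can stop, and how.

    ``SCAN_BOUNDS_REACHED`` is certified by a feasible point
    (loss clearly below the threshold) whose ``theta_i`` sits within
    ``scan_tol`` of — or beyond — the active scan bound: such a point
    proves the confidence interval leaves the scanned region, regardless
    of the optimizer's path.  ``BORDER_FOUND_BY_SCAN_TOL`` requires the
    outer loop's endpoint estimate to have moved by less than
    ``scan_tol`` while the constraint is active to within ``loss_tol``.
    Anything else returns ``CONTINUE``.
    """
    crit = request.threshold.loss_crit
    if best_feasible is not None:
        x, loss_val = best_feasible
        xi = float(np.asarray(x)[request.index]) if np.ndim(x) else float(x)
        if request.direction == "lower":
            at_bound = xi <= scan_bound + request.scan_tol
        else:
            at_bound = xi >= scan_bound - request.scan_tol
        if at_bound and loss_val < crit - request.loss_tol:
            return SCAN_BOUNDS_REACHED
    if (
        endpoint_estimate is not None
        and previous_estimate is not None
        and endpoint_loss is not None
        and abs(endpoint_estimate - previous_estimate) < request.scan_tol
        and abs(endpoint_loss - crit) <= request.loss_tol
    ):
        return BORDER_FOUND_BY_SCAN_TOL
    return CONTINUE


def _inner_minimize(fun, x0, bounds, local_alg, maxfev, xatol, fatol):
    """One unconstrained (box-bounded) subproblem solve."""
    if callable(local_alg):
        return local_alg(fun, x0, bounds=bounds, maxfev=maxfev)
    method = str(local_alg).lower()
    if method == "nelder-mead":
        options = {
            "maxfev": maxfev,
            "xatol": xatol,
            "fatol": fatol,
            "initial_simplex": initial_simplex(np.asarray(x0, dtype=float), bounds),
        }
    elif method == "powell":
        options = {"maxfev": maxfev, "xtol": xatol, "ftol": fatol}
    else:
        options = {}
    return optimize.minimize(fun, x0, method=local_alg, bounds=bounds, options=options)


def find_endpoint(request: EndpointRequest) -> EndpointResult:
    """Search for one confidence-interval endpoint.

    Runs the outer augmented-Lagrangian loop: each iteration minimizes
    :func:`augmented_objective` over the parameter box (the target
    parameter additionally boxed by the scan bounds), then updates the
    multiplier ``mu <- max(0, mu + rho * g)`` and grows the penalty
    ``rho`` tenfold whenever the constraint violation fails to shrink by
    a factor of four.  Terminates with exactly one of the three statuses.
    """
    req = request
    ev = req.evaluator
    crit = req.threshold.loss_crit
    sign = req.sign
    i = req.index
    scales = req.scales
    start_calls = ev.call_count

    x0 = np.array(
        [to_search_scale(v, s, index=j) for j, (v, s) in enumerate(zip(req.theta_init, scales))]
    )

    # best feasible point seen, extreme in the direction of travel
    best: dict = {"x": None, "loss": np.inf}

    def loss_search(x: np.ndarray) -> float:
        val = ev(vector_from_search(x, scales))
        if val < crit - req.loss_tol:
            if best["x"] is None or sign * x[i] < sign * best["x"][i]:
                best["x"] = np.array(x)
                best["loss"] = val
        return val

    l0 = loss_search(x0)
    if not l0 < crit:
        raise InfeasibleStartError(
            f"loss(theta_init) = {l0} is not below loss_crit = {crit}; "
            "refit the model or raise loss_crit"
        )

    bounds = [tuple(b) for b in req.theta_bounds]
    lo_i = max(bounds[i][0], req.scan_bounds[0])
    hi_i = min(bounds[i][1], req.scan_bounds[1])
    bounds[i] = (lo_i, hi_i)
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    xatol = req.scan_tol * 1e-2
    fatol = req.scan_tol * 1e-2
    inner_cap = max(400 * x0.size, 200)

    mu = 0.0
    rho = _RHO_INIT
    prev_violation = np.inf
    prev_est: Optional[float] = None
    x = x0.copy()
    status = MAX_ITER_STOP
    trace: List[Tuple[int, float, float, float, float]] = []
    x_star: Optional[np.ndarray] = None
    l_star = np.inf

    for outer in range(_MAX_OUTER):
        used = ev.call_count - start_calls
        remaining = req.max_evals - used
        if remaining <= 0:
            status = MAX_ITER_STOP
            break

        def aug(xx, _mu=mu, _rho=rho):
            g = loss_search(xx) - crit
            return sign * xx[i] + _psi(g, _mu, _rho)

        res = _inner_minimize(
            aug, x, bounds, req.local_alg, maxfev=int(min(inner_cap, remaining)), xatol=xatol, fatol=fatol
        )
        x = np.clip(np.asarray(res.x, dtype=float), [b[0] for b in bounds], [b[1] for b in bounds])
        lx = loss_search(x)
        g = lx - crit
        est = float(x[i])
        trace.append((outer, est, lx, mu, rho))

        stat = certify_termination(
            None if best["x"] is None else (best["x"], best["loss"]),
            req.active_scan_bound,
            req,
            endpoint_estimate=est,
            previous_estimate=prev_est,
            endpoint_loss=lx,
        )
        if stat != CONTINUE:
            status = stat
            x_star, l_star = x, lx
            break

        if (
            prev_est is not None
            and abs(est - prev_est) < req.scan_tol
            and g < -req.loss_tol
        ):
            # stalled with an inactive constraint: flat profile region or a
            # vanishing directional derivative at the boundary
            logger.warning(
                "endpoint estimate stalled at %.6g with inactive constraint "
                "(loss %.6g < loss_crit %.6g); continuing",
                est,
                lx,
                crit,
            )

        mu = max(0.0, mu + rho * g)
        violation = max(g, 0.0)
        if violation > 0.0 and violation > prev_violation / 4.0:
            rho = min(rho * _RHO_GROWTH, _RHO_MAX)
        if violation > 0.0:
            prev_violation = violation
        prev_est = est

    loss_calls = ev.call_count - start_calls
    if status == BORDER_FOUND_BY_SCAN_TOL and x_star is not None:
        natural = vector_from_search(x_star, scales)
        return EndpointResult(
            endpoint=float(natural[i]),
            status=status,
            loss_calls=loss_calls,
            argument=natural,
            trace=trace,
            direction=req.direction,
            index=i,
        )
    return EndpointResult(
        endpoint=None,
        status=status,
        loss_calls=loss_calls,
        argument=None,
        trace=trace,
        direction=req.direction,
        index=i,
    )


def _resolve_common(
    evaluator,
    theta_init,
    index,
    loss_crit,
    alpha,
    df,
    l_min,
    scan_bounds,
    theta_bounds,
    scales,
    scan_tol,
    loss_tol,
):
    theta_init = np.asarray(theta_init, dtype=float)
    m = theta_init.size
    if scales is None:
        scales = ["direct"] * m
    elif isinstance(scales, str):
        scales = [scales] * m
    scales = list(scales)

    if l_min is None:
        l_min = evaluator(theta_init)
    threshold = make_threshold(l_min, alpha=alpha, df=df, loss_crit=loss_crit)

    if scan_bounds is None:
        scan_bounds = (
            to_search_scale(DEFAULT_SCAN_BOUNDS[0], scales[index], index),
            to_search_scale(DEFAULT_SCAN_BOUNDS[1], scales[index], index),
        )
    if theta_bounds is None:
        theta_bounds = [DEFAULT_THETA_BOUND] * m
    if loss_tol is None:
        loss_tol = 1e-3 * max(threshold.delta, 1e-12)
    return theta_init, scales, threshold, tuple(scan_bounds), list(theta_bounds), scan_tol, loss_tol


def find_endpoint_for(
    evaluator: LossEvaluator,
    theta_init,
    index: int,
    direction: str,
    *,
    loss_crit: Optional[float] = None,
    alpha: Optional[float] = None,
    df: int = 1,
    l_min: Optional[float] = None,
    scan_bounds: Optional[Tuple[float, float]] = None,
    theta_bounds: Optional[Sequence[Tuple[float, float]]] = None,
    scales=None,
    scan_tol: float = 1e-3,
    loss_tol: Optional[float] = None,
    max_evals: int = 100_000,
    local_alg="nelder-mead",
) -> EndpointResult:
    """Convenience wrapper building an :class:`EndpointRequest` from loose arguments."""
    theta_init, scales, threshold, scan_bounds, theta_bounds, scan_tol, loss_tol = _resolve_common(
        evaluator, theta_init, index, loss_crit, alpha, df, l_min, scan_bounds, theta_bounds,
        scales, scan_tol, loss_tol,
    )
    req = EndpointRequest(
        evaluator=evaluator,
        theta_init=theta_init,
        index=index,
        direction=direction,
        threshold=threshold,
        scan_bounds=scan_bounds,
        theta_bounds=theta_bounds,
        scales=scales,
        scan_tol=scan_tol,
        loss_tol=loss_tol,
        max_evals=max_evals,
        local_alg=local_alg,
    )
    return find_endpoint(req)


def find_interval(
    evaluator: LossEvaluator,
    theta_init,
    index: int,
    *,
    loss_crit: Optional[float] = None,
    alpha: Optional[float] = None,
    df: int = 1,
    l_min: Optional[float] = None,
    scan_bounds: Optional[Tuple[float, float]] = None,
    theta_bounds: Optional[Sequence[Tuple[float, float]]] = None,
    scales=None,
    scan_tol: float = 1e-3,
    loss_tol: Optional[float] = None,
    max_evals: int = 100_000,
    local_alg="nelder-mead",
) -> IntervalResult:
    """Compute both confidence-interval endpoints for one parameter.

    Two independent :func:`find_endpoint` runs (lower, then upper), each
    restarted from ``theta_init``.  ``identifiable_within_bounds`` is
    true iff both searches converged to an endpoint inside the scan
    bounds.

    The threshold is given either directly as ``loss_crit`` or as
    ``(alpha, df)`` relative to ``l_min`` (the loss at ``theta_init``
    unless overridden); a direct ``loss_crit`` wins.
    """
    theta_init, scales, threshold, scan_bounds, theta_bounds, scan_tol, loss_tol = _resolve_common(
        evaluator, theta_init, index, loss_crit, alpha, df, l_min, scan_bounds, theta_bounds,
        scales, scan_tol, loss_tol,
    )
    results = {}
    for direction in ("lower", "upper"):
        req = EndpointRequest(
            evaluator=evaluator,
            theta_init=theta_init,
            index=index,
            direction=direction,
            threshold=threshold,
            scan_bounds=scan_bounds,
            theta_bounds=theta_bounds,
            scales=scales,
            scan_tol=scan_tol,
            loss_tol=loss_tol,
            max_evals=max_evals,
            local_alg=local_alg,
        )
        results[direction] = find_endpoint(req)
    return IntervalResult(
        lower=results["lower"],
        upper=results["upper"],
        index=index,
        threshold=threshold,
        scan_bounds=scan_bounds,
        scale=scales[index],
    )
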