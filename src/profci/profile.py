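"""Stepwise profile-likelihood computation.

The profile likelihood of parameter ``i`` is

    l_PL(theta_i) = min over theta_{j != i} of l(theta),

computed here on a fixed grid by re-optimizing the nuisance parameters
at each grid point, warm-started from the neighbouring point's argmin
(sweeping outward from the starting value in both directions).  This is
the classical, expensive approach; inside this package it serves as the
brute-force oracle against which the constrained-optimization endpoint
search is validated, and as the curve behind profile plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize

from ._optim import initial_simplex
from .errors import DomainError
from .objective import LossEvaluator

__all__ = ["ParameterProfile", "compute_profile", "crossing_from_profile"]


@dataclass
class ParameterProfile:
    """A profile-likelihood curve on a grid.

    ``argmins`` holds the nuisance vectors (full length-``m`` vectors
    with ``theta_i`` fixed at the grid value) achieving each profile
    value.  ``center`` is the starting ``theta_i`` (usually the MLE),
    needed to decide which side of the profile a crossing lies on.
    """

    index: int
    grid: np.ndarray
    values: np.ndarray
    argmins: List[np.ndarray] = field(default_factory=list)
    loss_calls: int = 0
    center: float = 0.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"grid": self.grid, "l_pl": self.values})

    def export_csv(self, path) -> None:
        df = self.to_dataframe()
        df["loss_calls"] = self.loss_calls
        df.to_csv(path, index=False)


def _reoptimize(evaluator, theta_fixed, index, nuisance_start, local_alg, xatol, fatol, maxfev):
    """Minimize the loss over the nuisance parameters at fixed theta_i."""
    free = [j for j in range(theta_fixed.size) if j != index]

    def partial(z):
        theta = theta_fixed.copy()
        theta[free] = z
        return evaluator(theta)

    res = optimize.minimize(
        partial,
        nuisance_start,
        method=local_alg,
        options={
            "xatol": xatol,
            "fatol": fatol,
            "maxfev": maxfev,
            "initial_simplex": initial_simplex(np.asarray(nuisance_start, dtype=float)),
        },
    )
    theta = theta_fixed.copy()
    theta[free] = res.x
    return theta, float(res.fun)


def compute_profile(
    evaluator: LossEvaluator,
    theta_init: Sequence[float],
    index: int,
    grid: Sequence[float],
    local_alg: str = "nelder-mead",
    warm_start: bool = True,
    xatol: float = 1e-7,
    fatol: float = 1e-9,
    maxfev_per_point: int = 2000,
) -> ParameterProfile:
    """Profile ``theta_index`` over ``grid`` by nuisance re-optimization.

    The sweep starts at the grid point nearest ``theta_init[index]`` and
    moves outward in both directions; with ``warm_start`` each point's
    nuisance optimization starts from the previous point's argmin
    (set ``warm_start=False`` to cold-start every point from
    ``theta_init``, useful for robustness checks).  An optimizer failure
    at a grid point records ``+inf`` with a warning instead of aborting.
    """
    theta_init = np.asarray(theta_init, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("grid must be non-empty")
    if not np.all(np.diff(grid) > 0):
        raise DomainError("grid must be strictly increasing")
    m = theta_init.size
    if not 0 <= index < m:
        raise DomainError(f"index {index} outside 0..{m - 1}")

    start_calls = evaluator.call_count
    values = np.full(grid.size, np.inf)
    argmins: List[Optional[np.ndarray]] = [None] * grid.size

    if m == 1:
        # no nuisance parameters: the profile is the loss itself
        for k, g in enumerate(grid):
            values[k] = evaluator(np.array([g]))
            argmins[k] = np.array([g])
        return ParameterProfile(
            index=index,
            grid=grid,
            values=values,
            argmins=argmins,
            loss_calls=evaluator.call_count - start_calls,
            center=float(theta_init[0]),
        )

    free = [j for j in range(m) if j != index]
    k0 = int(np.argmin(np.abs(grid - theta_init[index])))

    def sweep(order):
        nuisance = theta_init[free].copy()
        for k in order:
            theta_fixed = theta_init.copy()
            theta_fixed[index] = grid[k]
            start = nuisance if warm_start else theta_init[free]
            try:
                theta_opt, val = _reoptimize(
                    evaluator, theta_fixed, index, start, local_alg, xatol, fatol, maxfev_per_point
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"profile re-optimization failed at grid point {grid[k]}: {exc}")
                continue
            if not np.isfinite(val):
                warnings.warn(f"profile value non-finite at grid point {grid[k]}")
            values[k] = val
            argmins[k] = theta_opt
            if np.isfinite(val):
                nuisance = theta_opt[free]

    sweep(range(k0, grid.size))  # outward to the right
    sweep(range(k0 - 1, -1, -1))  # outward to the left

    return ParameterProfile(
        index=index,
        grid=grid,
        values=values,
        argmins=argmins,
        loss_calls=evaluator.call_count - start_calls,
        center=float(theta_init[index]),
    )


def crossing_from_profile(
    profile: ParameterProfile, loss_crit: float, side: str
) -> Optional[float]:
    """Interpolated crossing of the profile with the threshold.

    Finds the outermost sign change of ``values - loss_crit`` on the
    requested ``side`` ("lower"/"upper") of the profile center and
    returns the linear interpolation of the crossing point; ``None`` if
    the profile never crosses the threshold on that side
    (non-identifiable within the grid).
    """
    if side not in ("lower", "upper"):
        raise DomainError(f"side must be 'lower' or 'upper', got {side!r}")
    if not np.isfinite(loss_crit):
        raise DomainError("loss_crit must be finite")
    g = profile.grid
    v = profile.values
    c = profile.center
    if not (g[0] <= c <= g[-1]):
        raise DomainError(
            f"profile grid [{g[0]}, {g[-1]}] does not bracket the center {c}"
        )
    d = v - loss_crit
    if side == "upper":
        ks = [k for k in range(len(g) - 1) if g[k + 1] >= c]
        order = reversed(ks)  # outermost pair first
    else:
        ks = [k for k in range(len(g) - 1) if g[k] <= c]
        order = iter(ks)  # outermost (leftmost) pair first
    for k in order:
        a, b = d[k], d[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0 and b == 0.0:
            return float(g[k + 1] if side == "upper" else g[k])
        if a * b <= 0.0 and (a != 0.0 or b != 0.0):
            if a == b:
                return float(g[k])
            t = a / (a - b)
            return float(g[k] + t * (g[k + 1] - g[k]))
    return None
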