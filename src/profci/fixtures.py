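"""Bundled test problems and a synthetic nonlinear-regression generator.

Three closed-form toy losses with known geometry:

* :func:`booth` — a well-conditioned quadratic bowl; every parameter is
  identifiable, and the profile of ``theta_1`` is exactly
  ``1.8 * (1 - theta_1)**2``.
* :func:`rosenbrock` — the banana valley; its ``theta_1`` profile,
  ``(1 - theta_1)**2``, stays far below any generous threshold on a
  moderate scan range, making it the canonical
  non-identifiable-within-bounds case.
* :func:`readme_quadratic` — ``5 + (t1-3)^2 + (t1-t2-1)^2``, whose
  confidence-region geometry is solvable by hand (endpoints 1 and 5 for
  ``theta_1`` at threshold 9).

Plus a Gaussian-noise data generator for regression observables, the
weighted-sum-of-squared-residuals (WSSR) negative log-likelihood it
implies, and a small MLE fit helper — enough to exercise every
algorithmic module without any external download.  The observables are
closed-form (a line, a biexponential decay), not ODE solutions, so the
whole suite runs in seconds; the nearly-degenerate biexponential with
``k1 == k2`` reproduces the flat-profile pathology of real kinetic
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, FitError
from .objective import LossEvaluator, counted_evaluator

__all__ = [
    "SyntheticDataset",
    "ToyProblem",
    "booth",
    "rosenbrock",
    "readme_quadratic",
    "make_linear_dataset",
    "make_biexponential_dataset",
    "linear_model",
    "biexponential_model",
    "wssr_loss",
    "fit_mle",
    "toy_problems",
]


# ---------------------------------------------------------------------------
# toy losses


def booth(theta: Sequence[float]) -> float:
    """Booth function ``(t1 + 2 t2 - 7)^2 + (2 t1 + t2 - 5)^2``; minimum 0 at (1, 3)."""
    t1, t2 = _two(theta)
    return (t1 + 2 * t2 - 7.0) ** 2 + (2 * t1 + t2 - 5.0) ** 2


def rosenbrock(theta: Sequence[float]) -> float:
    """Rosenbrock function ``(1 - t1)^2 + 100 (t2 - t1^2)^2``; minimum 0 at (1, 1)."""
    t1, t2 = _two(theta)
    return (1.0 - t1) ** 2 + 100.0 * (t2 - t1 ** 2) ** 2


def readme_quadratic(theta: Sequence[float]) -> float:
    """``5 + (t1 - 3)^2 + (t1 - t2 - 1)^2``; minimum 5 at (3, 2)."""
    t1, t2 = _two(theta)
    return 5.0 + (t1 - 3.0) ** 2 + (t1 - t2 - 1.0) ** 2


def _two(theta) -> Tuple[float, float]:
    theta = np.asarray(theta, dtype=float)
    if theta.size != 2:
        raise DomainError(f"expected a 2-vector, got length {theta.size}")
    return float(theta[0]), float(theta[1])


@dataclass
class ToyProblem:
    """A bundled loss with its search setup and (when known) exact endpoints.

    ``known_endpoints`` maps a 0-based parameter index to a
    ``(lower, upper)`` pair in natural scale, each entry possibly
    ``None`` when the interval leaves ``scan_bounds`` on that side;
    ``provenance`` says how the numbers were derived.
    """

    name: str
    loss: Callable
    theta_init: np.ndarray
    loss_crit: float
    scan_bounds: Tuple[float, float]
    known_endpoints: Dict[int, Tuple[Optional[float], Optional[float]]] = field(default_factory=dict)
    provenance: str = ""

    def evaluator(self, record_trace: bool = False) -> LossEvaluator:
        return counted_evaluator(self.loss, record_trace=record_trace)


def toy_problems() -> Dict[str, ToyProblem]:
    """The bundled problem registry, keyed by name."""
    r = float(np.sqrt(200.0 / 1.8))  # Booth profile crossing half-width at threshold 200
    s = float(2.0 * np.sqrt(2.0))
    return {
        "readme_quadratic": ToyProblem(
            name="readme_quadratic",
            loss=readme_quadratic,
            theta_init=np.array([3.0, 2.0]),
            loss_crit=9.0,
            scan_bounds=(-100.0, 100.0),
            known_endpoints={0: (1.0, 5.0), 1: (2.0 - s, 2.0 + s)},
            provenance="analytic: constraint reduces to (t1-3)^2 <= 4 on the t1 profile",
        ),
        "booth": ToyProblem(
            name="booth",
            loss=booth,
            theta_init=np.array([1.0, 3.0]),
            loss_crit=200.0,
            scan_bounds=(-100.0, 100.0),
            known_endpoints={0: (1.0 - r, 1.0 + r), 1: (3.0 - r, 3.0 + r)},
            provenance="closed-form profiles 1.8(1-t1)^2 and 1.8(t2-3)^2",
        ),
        "rosenbrock": ToyProblem(
            name="rosenbrock",
            loss=rosenbrock,
            theta_init=np.array([1.0, 1.0]),
            loss_crit=200.0,
            scan_bounds=(-5.0, 5.0),
            known_endpoints={0: (None, None)},
            provenance="profile (1-t1)^2 <= 36 < 200 everywhere inside (-5, 5): no crossing",
        ),
    }


# ---------------------------------------------------------------------------
# synthetic data


@dataclass
class SyntheticDataset:
    """Observations of one or more components at shared time points.

    ``observations`` and ``sigmas`` are ``(n_components, k_times)``
    arrays; ``true_params`` is the generating parameter vector and
    ``seed`` the RNG seed, kept so a dataset can be regenerated
    bit-identically.
    """

    times: np.ndarray
    observations: np.ndarray
    sigmas: np.ndarray
    true_params: np.ndarray
    seed: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        self.sigmas = np.broadcast_to(
            np.asarray(self.sigmas, dtype=float), self.observations.shape
        ).copy()
        self.true_params = np.asarray(self.true_params, dtype=float)
        if np.any(~np.isfinite(self.observations)):
            raise DomainError("observations contain missing or non-finite entries")
        if np.any(self.sigmas <= 0):
            raise DomainError("sigmas must be strictly positive")

    def to_csv(self, path) -> None:
        import pandas as pd

        n, k = self.observations.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append(
                    {
                        "time": self.times[j],
                        "component": i,
                        "value": self.observations[i, j],
                        "sigma": self.sigmas[i, j],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, true_params=(), seed: int = 0) -> "SyntheticDataset":
        import pandas as pd

        df = pd.read_csv(path)
        comps = sorted(df["component"].unique())
        times = np.sort(df[df["component"] == comps[0]]["time"].to_numpy())
        obs = np.empty((len(comps), times.size))
        sig = np.empty_like(obs)
        for i, c in enumerate(comps):
            sub = df[df["component"] == c].sort_values("time")
            obs[i] = sub["value"].to_numpy()
            sig[i] = sub["sigma"].to_numpy()
        return cls(times=times, observations=obs, sigmas=sig, true_params=np.asarray(true_params, dtype=float), seed=seed)


def linear_model(params: Sequence[float], times: np.ndarray) -> np.ndarray:
    """``y(t) = slope * t + intercept`` as a single observed component."""
    slope, intercept = np.asarray(params, dtype=float)
    return (intercept + slope * np.asarray(times))[None, :]


def biexponential_model(params: Sequence[float], times: np.ndarray) -> np.ndarray:
    """``y(t) = a1 exp(-k1 t) + a2 exp(-k2 t)`` as a single component."""
    a1, k1, a2, k2 = np.asarray(params, dtype=float)
    t = np.asarray(times)
    return (a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t))[None, :]


def make_linear_dataset(
    slope: float,
    intercept: float,
    times: Sequence[float],
    sigma: float,
    seed: int,
) -> SyntheticDataset:
    """Noisy straight-line observations with additive Gaussian error."""
    if not sigma > 0:
        raise DomainError("sigma must be > 0")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise DomainError("times must be non-empty")
    rng = np.random.default_rng(seed)
    true = np.array([slope, intercept], dtype=float)
    clean = linear_model(true, times)
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    return SyntheticDataset(
        times=times, observations=noisy, sigmas=np.full_like(clean, sigma), true_params=true, seed=seed
    )


def make_biexponential_dataset(
    a1: float,
    k1: float,
    a2: float,
    k2: float,
    times: Sequence[float],
    sigma: float,
    seed: int,
) -> SyntheticDataset:
    """Noisy two-exponential decay observations.

    With ``k1 == k2`` the amplitudes enter only through ``a1 + a2`` —
    the exact exchange degeneracy of a kinetic model whose data cannot
    separate two pools, giving flat profiles for ``a1`` and ``a2``.
    """
    if not (k1 > 0 and k2 > 0):
        raise DomainError("rates k1, k2 must be > 0")
    if not sigma > 0:
        raise DomainError("sigma must be > 0")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    true = np.array([a1, k1, a2, k2], dtype=float)
    clean = biexponential_model(true, times)
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    return SyntheticDataset(
        times=times, observations=noisy, sigmas=np.full_like(clean, sigma), true_params=true, seed=seed
    )


def wssr_loss(
    dataset: SyntheticDataset,
    model: Callable[[Sequence[float], np.ndarray], np.ndarray],
    record_trace: bool = False,
) -> LossEvaluator:
    """Weighted sum-of-squared-residuals loss for additive Gaussian error.

    ``l(theta) = sum_ij ((obs_ij - y_i(theta, t_j)) / sigma_ij)^2`` —
    the negative log-likelihood (up to a constant) when the noise SDs
    are known.  Returned as a counted evaluator.
    """
    obs = dataset.observations
    sig = dataset.sigmas
    times = dataset.times

    def raw(theta):
        pred = np.atleast_2d(np.asarray(model(theta, times), dtype=float))
        if pred.shape != obs.shape:
            raise DomainError(
                f"model output shape {pred.shape} does not match observations {obs.shape}"
            )
        return float(np.sum(((obs - pred) / sig) ** 2))

    return counted_evaluator(raw, record_trace=record_trace)


def fit_mle(
    evaluator: LossEvaluator,
    start: Sequence[float],
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    local_alg: str = "nelder-mead",
    xatol: float = 1e-9,
    fatol: float = 1e-12,
    maxfev: int = 20000,
) -> Tuple[np.ndarray, float]:
    """Point estimate by local minimization of the loss.

    Returns ``(theta_hat, l_min)``.  Raises :class:`FitError` carrying
    the best point seen when the optimizer reports failure.
    """
    from scipy import optimize

    start = np.asarray(start, dtype=float)
    res = optimize.minimize(
        evaluator,
        start,
        method=local_alg,
        bounds=bounds,
        options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
    )
    if not res.success:
        raise FitError(
            f"MLE fit did not converge: {res.message}", best_theta=res.x, best_loss=float(res.fun)
        )
    return np.asarray(res.x, dtype=float), float(res.fun)
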