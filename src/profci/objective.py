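"""Counted, guarded loss evaluators and likelihood-ratio thresholds.

The package treats the user's negative log-likelihood ``l(theta)`` as an
opaque scalar function.  Two pieces of machinery are layered on top:

* :class:`LossEvaluator` — wraps the raw function, counts every call
  (the hardware-independent efficiency metric used throughout), and maps
  numerical failures to a ``+inf`` sentinel so optimizers never see an
  exception from inside a stiff model.
* :class:`ThresholdSpec` / :func:`make_threshold` — the likelihood-ratio
  confidence threshold ``loss_crit = l(theta_hat) + delta_alpha`` where
  ``delta_alpha`` is the ``alpha`` quantile of a chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["LossEvaluator", "ThresholdSpec", "counted_evaluator", "make_threshold"]


class LossEvaluator:
    """A counted, guarded wrapper around a scalar loss function.

    Parameters
    ----------
    raw_loss
        Callable mapping a length-``m`` parameter vector to a scalar
        negative log-likelihood.
    record_trace
        If true, every evaluation is appended to ``trace`` as a
        ``(theta_copy, loss)`` pair.

    Notes
    -----
    ``call_count`` increments by exactly one per evaluation, including
    failed ones.  Exceptions raised by ``raw_loss`` (an ODE solver blowing
    up, an overflow) and non-finite return values are reported as
    ``math.inf`` rather than propagated — with the single exception of
    :class:`~profci.errors.DomainError`, which marks a caller mistake and
    is re-raised.
    """

    def __init__(self, raw_loss: Callable[[np.ndarray], float], record_trace: bool = False):
        self._raw = raw_loss
        self.call_count: int = 0
        self.trace: Optional[List[Tuple[np.ndarray, float]]] = [] if record_trace else None

    def __call__(self, theta: Sequence[float]) -> float:
        theta = np.asarray(theta, dtype=float)
        self.call_count += 1
        try:
            value = float(self._raw(theta))
        except DomainError:
            raise
        except Exception:
            value = np.inf
        if not np.isfinite(value):
            value = np.inf
        if self.trace is not None:
            self.trace.append((theta.copy(), value))
        return value

    # alias used in prose-style call sites
    def evaluate(self, theta: Sequence[float]) -> float:
        return self(theta)

    def trace_dataframe(self):
        """Return the trace as a DataFrame (eval_index, theta_1..theta_m, loss)."""
        import pandas as pd

        if self.trace is None:
            raise DomainError("evaluator was created with record_trace=False")
        rows = []
        for k, (theta, loss) in enumerate(self.trace):
            row = {"eval_index": k}
            row.update({f"theta_{j + 1}": tj for j, tj in enumerate(theta)})
            row["loss"] = loss
            rows.append(row)
        return pd.DataFrame(rows)

    def export_trace(self, path) -> None:
        """Write the evaluation trace to a CSV file."""
        self.trace_dataframe().to_csv(path, index=False)


def counted_evaluator(raw_loss: Callable, record_trace: bool = False) -> LossEvaluator:
    """Wrap ``raw_loss`` into a :class:`LossEvaluator`."""
    return LossEvaluator(raw_loss, record_trace=record_trace)


@dataclass(frozen=True)
class ThresholdSpec:
    """Likelihood-ratio threshold for a profile-likelihood confidence interval.

    ``loss_crit = l_min + delta``, where ``delta`` is the ``alpha``
    quantile of the chi-square distribution with ``df`` degrees of
    freedom.  ``alpha``/``df`` are ``None`` when the threshold was given
    directly as ``loss_crit``.
    """

    l_min: float
    loss_crit: float
    alpha: Optional[float] = None
    df: Optional[int] = None

    @property
    def delta(self) -> float:
        """The offset ``loss_crit - l_min`` above the optimum."""
        return self.loss_crit - self.l_min

    def __post_init__(self):
        if not np.isfinite(self.l_min):
            raise DomainError(f"l_min must be finite, got {self.l_min}")
        if not np.isfinite(self.loss_crit):
            raise DomainError(f"loss_crit must be finite, got {self.loss_crit}")


def make_threshold(
    l_min: float,
    alpha: Optional[float] = None,
    df: int = 1,
    loss_crit: Optional[float] = None,
) -> ThresholdSpec:
    """Build the confidence threshold above the loss optimum.

    Exactly mirrors the likelihood-ratio construction: the confidence
    region at level ``alpha`` is ``{theta : l(theta) <= l_min + delta}``
    with ``delta`` the ``alpha`` chi-square quantile.  ``df=1`` gives the
    usual pointwise interval for a single parameter.

    A direct ``loss_crit`` may be given instead of (or in addition to)
    ``alpha``; when both are present the direct value wins.
    """
    if not np.isfinite(l_min):
        raise DomainError(f"l_min must be finite, got {l_min}")
    if loss_crit is not None:
        return ThresholdSpec(l_min=float(l_min), loss_crit=float(loss_crit))
    if alpha is None:
        raise DomainError("either alpha or loss_crit must be given")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if df < 1:
        raise DomainError(f"df must be a positive integer, got {df}")
    delta = float(stats.chi2.ppf(alpha, df))
    return ThresholdSpec(l_min=float(l_min), loss_crit=float(l_min) + delta, alpha=float(alpha), df=int(df))
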