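"""Parameter-scale transforms between natural and search space.

The endpoint search may run in a transformed space per parameter:

* ``direct`` — identity,
* ``log`` — base-10 logarithm, for strictly positive parameters spanning
  orders of magnitude (rate constants, concentrations),
* ``logit`` — ``log(v / (1 - v))``, for parameters confined to (0, 1)
  (fractions, probabilities).

All three maps are strictly increasing, so interval endpoints keep their
ordering across scales.  Scan bounds and ``scan_tol`` are interpreted in
the search scale; reported endpoints are always converted back to the
natural scale.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "SCALES",
    "to_search_scale",
    "from_search_scale",
    "vector_to_search",
    "vector_from_search",
    "validate_scale",
]

SCALES = ("direct", "log", "logit")


def validate_scale(scale: str) -> str:
    if scale not in SCALES:
        raise DomainError(f"unknown scale {scale!r}; expected one of {SCALES}")
    return scale


def _where(index: Optional[int]) -> str:
    return "" if index is None else f" (parameter index {index})"


def to_search_scale(value: float, scale: str, index: Optional[int] = None) -> float:
    """Map a natural-scale value into the search scale."""
    validate_scale(scale)
    value = float(value)
    if scale == "direct":
        return value
    if scale == "log":
        if not value > 0.0:
            raise DomainError(f"log scale requires value > 0, got {value}{_where(index)}")
        return math.log10(value)
    if not (0.0 < value < 1.0):
        raise DomainError(f"logit scale requires value in (0, 1), got {value}{_where(index)}")
    return math.log(value / (1.0 - value))


def from_search_scale(value: float, scale: str) -> float:
    """Inverse of :func:`to_search_scale`."""
    validate_scale(scale)
    value = float(value)
    if scale == "direct":
        return value
    if scale == "log":
        return 10.0 ** value
    # numerically stable logistic
    if value >= 0:
        return 1.0 / (1.0 + math.exp(-value))
    e = math.exp(value)
    return e / (1.0 + e)


def vector_to_search(theta: Sequence[float], scales: Sequence[str]) -> np.ndarray:
    return np.array([to_search_scale(v, s, index=i) for i, (v, s) in enumerate(zip(theta, scales))])


def vector_from_search(x: Sequence[float], scales: Sequence[str]) -> np.ndarray:
    return np.array([from_search_scale(v, s) for v, s in zip(x, scales)])
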