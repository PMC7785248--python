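"""Shared derivative-free optimizer plumbing.

scipy's Nelder-Mead seeds its simplex with a relative 5% perturbation of
the start point, which degenerates when a coordinate sits near zero (a
frequent situation for warm-started nuisance parameters).  The helper
here builds an explicit simplex with an absolute step floor, stepping
away from any nearby box face.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

_REL_STEP = 0.05
_ABS_STEP = 0.1


def initial_simplex(
    x0: np.ndarray,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    rel: float = _REL_STEP,
    floor: float = _ABS_STEP,
) -> np.ndarray:
    """A non-degenerate starting simplex around ``x0``.

    Each vertex perturbs one coordinate by ``max(rel * |x0_j|, floor)``,
    flipping the step direction (and shrinking it if needed) to stay
    inside ``bounds``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    sim = np.tile(x0, (n + 1, 1))
    for j in range(n):
        step = max(rel * abs(x0[j]), floor)
        if bounds is not None:
            lo, hi = bounds[j]
            width = hi - lo
            step = min(step, 0.45 * width) if np.isfinite(width) else step
            if x0[j] + step > hi:
                step = -step
            if x0[j] + step < lo:  # box narrower than the step: center it
                step = 0.5 * (hi + lo) - x0[j] or 0.25 * width
        sim[j + 1, j] += step
    return sim
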