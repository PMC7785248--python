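"""Profile and search-path plots.

One figure style: the profile-likelihood curve (dotted), the confidence
threshold (dashed horizontal), endpoint markers — a filled red circle
for a converged endpoint, a black square where the search certified a
scan bound instead — and optionally the cloud of points the endpoint
search actually visited.
"""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .cico import BORDER_FOUND_BY_SCAN_TOL, SCAN_BOUNDS_REACHED, EndpointResult
from .objective import ThresholdSpec
from .profile import ParameterProfile

__all__ = ["plot_profile_with_endpoints"]


def plot_profile_with_endpoints(
    profile: ParameterProfile,
    threshold: ThresholdSpec,
    endpoints: Iterable[EndpointResult] = (),
    trace=None,
    path: Optional[str] = None,
    scan_bounds=None,
    ax=None,
):
    """Render a profile curve with its threshold and endpoint markers.

    ``trace`` may be a list of ``(theta_vector, loss)`` pairs (an
    evaluator trace); the visited ``theta_i`` values are scattered
    against their losses.  Returns the Matplotlib axes; when ``path``
    is given the figure is also written there.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(profile.grid, profile.values, ls=":", color="tab:blue", label="profile likelihood")
    ax.axhline(threshold.loss_crit, ls="--", color="gray", label="threshold")

    if trace:
        xs = [t[profile.index] for t, _ in trace]
        ys = [l for _, l in trace]
        ax.scatter(xs, ys, s=8, alpha=0.35, color="tab:orange", label="visited points", zorder=2)

    seen_labels = set()
    for ep in endpoints:
        if ep.status == BORDER_FOUND_BY_SCAN_TOL and ep.endpoint is not None:
            label = None if "endpoint" in seen_labels else "CI endpoint"
            seen_labels.add("endpoint")
            ax.plot([ep.endpoint], [threshold.loss_crit], "o", color="red", ms=9, label=label, zorder=3)
        elif ep.status == SCAN_BOUNDS_REACHED and scan_bounds is not None:
            bound = scan_bounds[0] if ep.direction == "lower" else scan_bounds[1]
            label = None if "bound" in seen_labels else "scan bound reached"
            seen_labels.add("bound")
            ax.plot([bound], [threshold.loss_crit], "s", color="black", ms=9, label=label, zorder=3)

    ax.set_xlabel(f"theta_{profile.index + 1}")
    ax.set_ylabel("loss")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
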