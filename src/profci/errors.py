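"""Exception hierarchy.

``DomainError`` marks caller mistakes (bad arguments, shape mismatches).
It deliberately propagates through :class:`~profci.objective.LossEvaluator`,
whereas numerical failures inside a user loss are absorbed into the
``+inf`` sentinel so that derivative-free optimizers can step through them.
"""


class ProfciError(Exception):
    """Base class for all package errors."""


class DomainError(ProfciError, ValueError):
    """An argument is outside its mathematical domain or mis-shaped."""


class InfeasibleStartError(ProfciError):
    """The starting point already violates the likelihood-ratio constraint.

    Raised when ``loss(theta_init) >= loss_crit``: the endpoint search has
    no feasible interior to start from.  Refit the model (so that
    ``theta_init`` is near the optimum) or raise ``loss_crit``.
    """


class FitError(ProfciError):
    """A point-estimate fit failed to converge.

    Carries the best parameter vector and loss seen so far in
    ``best_theta`` / ``best_loss``.
    """

    def __init__(self, message, best_theta=None, best_loss=None):
        super().__init__(message)
        self.best_theta = best_theta
        self.best_loss = best_loss
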