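"""Exception hierarchy for rbgof.

All validation failures derive from :class:`RbgofError` so callers can catch
package errors without masking programming errors, while each concrete class
also derives from the matching builtin (``ValueError`` / ``RuntimeError``).
"""


class RbgofError(Exception):
    """Base class for all rbgof errors."""


class DesignRankError(RbgofError, ValueError):
    """The design matrix is rank deficient (or has more columns than rows)."""


class CountError(RbgofError, ValueError):
    """Success counts violate 0 <= s_i <= n_i."""


class TrialsError(RbgofError, ValueError):
    """Trial counts violate n_i >= 1."""


class EmptyDataError(RbgofError, ValueError):
    """No observations supplied."""


class DomainError(RbgofError, ValueError):
    """A probability argument lies outside its admissible domain."""


class UndefinedRBError(RbgofError, RuntimeError):
    """The first discretization bin has zero prior content.

    The relative belief ratio of [0, delta*) is then 0/0 and the hypothesis
    assessment is meaningless at this resolution.  Remedies: enlarge the bin
    width ``delta_star``, enlarge the Monte Carlo size ``n_draws``, or switch
    to ``binning="prior_quantile"`` whose first bin holds prior mass
    ``delta_star`` by construction.
    """


class ConvergenceError(RbgofError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
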