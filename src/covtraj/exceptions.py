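"""Exception hierarchy for covtraj.

All library-raised errors derive from :class:`CovTrajError` so callers can
catch everything with one clause while still distinguishing sizing problems
from configuration mistakes or numerical breakdown.
"""


class CovTrajError(Exception):
    """Base class for all covtraj errors."""


class DimensionError(CovTrajError, ValueError):
    """Shapes of paired inputs do not agree (the message names both)."""


class ValidationError(CovTrajError, ValueError):
    """Input values violate a precondition (NaN/Inf entries, bad labels)."""


class ConfigError(CovTrajError, ValueError):
    """An option, policy name, or hyperparameter is invalid."""


class NumericError(CovTrajError, ArithmeticError):
    """A computation produced a non-finite or impossible value."""


class InternalStateError(CovTrajError, RuntimeError):
    """The variational state is internally inconsistent (should not happen)."""


class UndefinedResultError(CovTrajError, ValueError):
    """The requested quantity is undefined for this input.

    Raised e.g. for a rank correlation of a constant vector, an AUC with a
    single label class, or a cross-over point when the interaction effect is
    numerically zero (parallel trajectories).
    """


class UnsupportedCovariateError(CovTrajError, ValueError):
    """The covariate coding does not support the requested operation."""
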