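"""Exception hierarchy for semsgd.

All domain errors derive from :class:`SemError` so callers (and the CLI)
can distinguish anticipated modelling failures from programming bugs.
"""


class SemError(Exception):
    """Base class for all anticipated domain errors."""


class SpecificationError(SemError, ValueError):
    """The sparsity structure of the system is invalid (self-loop, empty equation, bad shapes)."""


class ShapeError(SemError, ValueError):
    """Matrix dimensions are inconsistent with the model specification."""


class AlgebraError(SemError, ValueError):
    """A linear-algebra step failed, e.g. (I - B~') is singular or ill-conditioned."""


class IdentificationError(SemError, ValueError):
    """An equation fails the order condition and cannot be estimated by 2SLS."""


class EstimationError(SemError, ValueError):
    """A regression step failed, e.g. a rank-deficient design matrix."""


class GenerationError(SemError, RuntimeError):
    """The synthetic generator exhausted its resampling budget."""


class DivergenceError(SemError, RuntimeError):
    """SGD produced a non-finite loss; training was aborted."""


class UsageError(SemError, ValueError):
    """Arguments are inconsistent with the requested operation."""
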