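"""Exception hierarchy.

All package errors derive from :class:`DebranchError` so callers can catch
one base class; subclasses map onto the distinct failure modes of the
workflow (parsing, invariant violations, solver states, configuration).
"""


class DebranchError(Exception):
    """Base class for all errors raised by debranch."""


class FormatError(DebranchError):
    """A file could not be parsed under the named standard."""


class ModelValidationError(DebranchError):
    """A model invariant (e.g. lb <= ub) is violated."""


class ConflictError(DebranchError):
    """An extension re-declares an existing reaction id without replace."""


class ParameterError(DebranchError):
    """A numeric parameter is outside its admissible domain."""


class ExpressionLookupError(DebranchError):
    """No TPM value for the requested gene/condition pair."""


class ConfigurationError(DebranchError):
    """A preset or run configuration references missing ids/paths."""


class InfeasibleError(DebranchError):
    """The constrained LP has no feasible point."""


class UnboundedError(DebranchError):
    """The LP objective (or sampling region) is unbounded."""


class NormalizationError(DebranchError):
    """A weighted multi-objective term has a zero standalone optimum."""


class GenerationError(DebranchError):
    """The synthetic-data generator produced an invalid artifact."""
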