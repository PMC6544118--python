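"""Exception hierarchy for the opstoich pipeline.

Every stage raises a subclass of :class:`OpstoichError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class OpstoichError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(OpstoichError):
    """A table is missing a required column or has an unknown schema."""


class ValidationError(OpstoichError):
    """A record violates a field invariant (negative value, empty id, ...)."""


class CrossReferenceError(OpstoichError):
    """An identifier refers to a record that does not exist."""


class CalibrationError(OpstoichError):
    """Copy-number calibration cannot proceed (empty intersection, ...)."""


class QCError(OpstoichError):
    """Replicate-reproducibility QC cannot be computed."""


class StatisticError(OpstoichError):
    """A statistic is undefined for the given input (n too small, mean 0)."""


class KineticsError(OpstoichError):
    """A required kinetic parameter is missing."""


class GenerationError(OpstoichError):
    """The synthetic-data generator was given an infeasible configuration."""


class UsageError(OpstoichError):
    """An argument value is outside its documented domain."""
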