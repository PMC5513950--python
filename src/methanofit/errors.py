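"""Typed exceptions raised across the pipeline.

All validation failures raise a subclass of :class:`MethanofitError` so that
callers (and the CLI) can distinguish bad input (exit code 2) from a fitting
or sampling stage that did not converge (exit code 3).
"""


class MethanofitError(Exception):
    """Base class for all package errors."""


class SchemaError(MethanofitError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(MethanofitError):
    """A value violates a domain invariant (negative methane, bad time, ...)."""


class DuplicateKeyError(ValidationError):
    """Two observations share the same (replicate, time) key."""


class InsufficientDataError(ValidationError):
    """Fewer distinct time points than required for a three-parameter fit."""


class DegenerateDataError(MethanofitError):
    """The series carries no kinetic signal (constant or all-zero methane)."""


class ConfigurationError(MethanofitError):
    """Inconsistent pipeline settings (e.g. MLE outside the prior box)."""


class DegenerateProposalError(ConfigurationError):
    """MCMC proposal scale is zero or negative."""


class NonConvergenceError(MethanofitError):
    """A stage failed to converge and no usable fallback exists."""
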