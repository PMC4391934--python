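"""Exception hierarchy for the qdki67 pipeline."""


class QDKi67Error(Exception):
    """Base class for all package errors."""


class InvalidParameterError(QDKi67Error, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(QDKi67Error):
    """A file's structure does not match the declared layout."""


class ValidationError(QDKi67Error, ValueError):
    """Data violates an invariant (negative intensity, grid mismatch, ...)."""


class IllConditionedLibraryError(QDKi67Error):
    """Endmember matrix is rank-deficient or numerically singular."""


class InfeasibleScanError(QDKi67Error):
    """No candidate cut-point leaves both groups large enough."""


class NoSignalError(QDKi67Error):
    """Survival data contain no events, so no rank statistic exists."""


class DegenerateCoreError(QDKi67Error):
    """A core has zero CK signal; its Ki67/CK ratio is undefined."""


class ConvergenceError(QDKi67Error):
    """Iterative fit failed to converge."""


class SeparationError(ConvergenceError):
    """Monotone partial likelihood: a covariate perfectly separates outcomes."""


class SchemaError(QDKi67Error):
    """A cohort table is missing a mandatory column."""
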