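"""Exception hierarchy.

Every failure mode callers are expected to handle has a named class so the
CLI can map it to a stable exit message and tests can assert on the type.
"""


class PhalanxError(Exception):
    """Base class for all package errors."""


class ConfigError(PhalanxError):
    """Invalid configuration value or combination."""


class CalibrationError(PhalanxError):
    """The noise moment system has no positive solution.

    Carries the name of the violated constraint in the message.
    """


class MixtureFitError(PhalanxError):
    """Mixture calibration did not reach the target accuracy.

    Attributes
    ----------
    params : tuple | None
        Best-found (pi_affected, delta_shift, base_sd).
    residuals : tuple | None
        Relative errors of (mean, sd, flag prevalence) at ``params``.
    """

    def __init__(self, message, params=None, residuals=None):
        super().__init__(message)
        self.params = params
        self.residuals = residuals


class SchemaError(PhalanxError):
    """Input file does not match the documented schema."""


class SchemaVersionError(SchemaError):
    """Serialized artifact has an unsupported format version."""


class DuplicateRecordError(SchemaError):
    """Duplicate (subject_id, bone) or subject_id key in an input file."""


class ZeroLengthError(PhalanxError):
    """Landmark pair is coincident; bone length undefined."""


class AgeRangeError(PhalanxError):
    """Bone age outside the supported [0, 18] year range."""


class UnavailableGroupError(PhalanxError):
    """Reference table cannot supply a usable SD for the requested group."""


class UndefinedCorrelationError(PhalanxError):
    """Correlation undefined because a variable (or residual) has zero variance."""


class NotPositiveDefiniteError(PhalanxError):
    """Implied correlation matrix is not positive definite."""
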