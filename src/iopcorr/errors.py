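"""Exception hierarchy shared by all iopcorr modules."""


class IopcorrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IopcorrError):
    """Input table is missing a mandatory column or has an unusable header."""


class RecordValidationError(IopcorrError):
    """A field value violates the eye-record invariants."""


class DependencyError(IopcorrError):
    """A correction formula was asked to run without a required input field."""


class AlignmentError(IopcorrError):
    """Two paired series do not have the same length."""


class InsufficientDataError(IopcorrError):
    """Too few observations for the requested statistic."""


class NumericError(IopcorrError):
    """A numeric routine failed (domain violation, non-convergence, NaN)."""


class ConfigError(IopcorrError):
    """A configuration file or override is malformed."""


class NonPhysiologicalIOPWarning(UserWarning):
    """A corrected IOP came out at or below 0 mmHg; value returned unclamped."""
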