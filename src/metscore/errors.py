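"""Exception hierarchy shared across the package."""


class MetscoreError(Exception):
    """Base class for all errors raised by metscore."""


class ParameterError(MetscoreError, ValueError):
    """An argument is outside its documented range or an unknown label."""


class DomainError(MetscoreError, ValueError):
    """Input values fall outside the mathematical domain of a transform."""

    def __init__(self, message: str, offending_ids=None):
        super().__init__(message)
        self.offending_ids = list(offending_ids) if offending_ids is not None else []


class DegenerateDataError(MetscoreError, ValueError):
    """Data carry no usable signal for the requested operation
    (zero variance, rank deficiency, monomorphic SNP, empty group)."""


class InsufficientDataError(MetscoreError, ValueError):
    """Fewer observations than the operation's minimum."""


class SchemaError(MetscoreError, ValueError):
    """A table is missing required columns or ids do not align across files."""
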