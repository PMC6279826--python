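"""Exception hierarchy.

Two families matter to callers (and to the CLI exit codes): validation-type
errors (bad arguments, schema mismatches, degenerate designs) and data-type
errors (unreadable files, missing metadata, unusable regions).
"""


class NailHgbError(Exception):
    """Base class for all package errors."""


class ValidationError(NailHgbError):
    """Invalid argument or precondition violation."""


class SchemaError(ValidationError):
    """Feature schema mismatch between a model and a feature vector."""

    def __init__(self, expected, got):
        self.expected = tuple(expected)
        self.got = tuple(got)
        missing = [n for n in expected if n not in got]
        extra = [n for n in got if n not in expected]
        super().__init__(
            f"feature schema mismatch: missing={missing} unexpected={extra}"
        )


class SingularityError(ValidationError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns, reason="rank-deficient design matrix"):
        self.columns = list(columns)
        super().__init__(f"{reason}: {self.columns}")


class DegenerateCalibrationError(ValidationError):
    """All calibration Hgb values identical; slope unidentifiable."""


class DataError(NailHgbError):
    """Problem with input data rather than with arguments."""


class FormatError(DataError):
    """File exists but cannot be decoded as an image."""


class MetadataError(DataError):
    """Mandatory capture metadata missing or invalid; names the field."""

    def __init__(self, field, message=None):
        self.field = field
        super().__init__(message or f"missing mandatory metadata field: {field!r}")


class GeometryError(DataError):
    """ROI rectangle outside image bounds; carries the offending coordinates."""


class UnusableROIError(DataError):
    """Too few pixels survive quality control for the ROI to be used."""


class SubjectUnusableError(DataError):
    """No usable nailbed ROI remains for a subject after quality control."""

    def __init__(self, message, reason_counts=None):
        self.reason_counts = dict(reason_counts or {})
        super().__init__(message)
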