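"""Exception hierarchy.

All package errors derive from :class:`CKBError` so callers can catch the
whole family; each subclass also inherits the closest builtin so idiomatic
``except ValueError`` style keeps working.
"""


class CKBError(Exception):
    """Base class for all errors raised by this package."""


class ShapeError(CKBError, ValueError):
    """Array dimensions are inconsistent with the operation's contract."""


class DegenerateInputError(CKBError, ValueError):
    """A vector with zero (or non-finite) norm was fed to a similarity op."""


class LabelError(CKBError, ValueError):
    """A class label is outside ``{0, ..., N-1}`` for the bank at hand."""


class ConfigurationError(CKBError, ValueError):
    """Invalid sizes, rates or generator parameters."""


class DataError(CKBError, ValueError):
    """A dataset violates a precondition (empty, single-class, too small)."""


class UninitializedStatisticsError(CKBError, RuntimeError):
    """Evaluation-mode normalization requested before any statistics exist."""


class CheckpointError(CKBError, ValueError):
    """A checkpoint bundle is missing fields or has an unknown version."""
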