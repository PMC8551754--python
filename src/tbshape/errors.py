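"""Exception hierarchy for the pipeline."""


class TbShapeError(Exception):
    """Base class for all package errors."""


class TraceFormatError(TbShapeError):
    """Raised when an input file cannot be parsed (bad timestamp, missing column)."""


class ValidationError(TbShapeError):
    """Raised when data or configuration violates an invariant."""


class FitError(TbShapeError):
    """Raised when a quantile smooth cannot be fitted (short segment, degenerate design)."""


class EvaluationRangeError(TbShapeError):
    """Raised when a fitted curve is evaluated outside its fitted span."""


class InsufficientDataError(TbShapeError):
    """Raised when a statistic requires more readings than are available."""
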