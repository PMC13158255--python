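"""Exception hierarchy shared across the package."""


class SpectraDietError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpectraDietError):
    """A file does not conform to the expected CSV dialect (missing columns etc.)."""


class DataError(SpectraDietError):
    """Structurally valid input with inconsistent content (grid mismatch, NaNs, ...)."""


class ValidationError(SpectraDietError):
    """A domain invariant is violated (inverted window, bad config value, ...)."""


class DegenerateInputError(SpectraDietError):
    """Input is valid but degenerate for the requested operation (zero-norm spectrum,
    empty grid after excision, fewer than two samples for a PCA)."""


class CoverageError(SpectraDietError):
    """A band window contains no grid point of the spectrum it is applied to."""


class StratificationError(SpectraDietError):
    """A class is too small to be split into both train and test partitions."""


class PipelineStageError(SpectraDietError):
    """Wraps any error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
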