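"""Exception hierarchy for littersim."""


class LitterSimError(Exception):
    """Base class for all littersim errors."""


class InvalidModelError(LitterSimError):
    """A coregionalization model violates a validity requirement (PSD, ranges)."""


class DegenerateInputError(LitterSimError):
    """Input data carry no usable variation (e.g. all values identical)."""


class InvalidTableError(LitterSimError):
    """An anamorphosis table is not strictly monotone."""


class FittingError(LitterSimError):
    """Variogram model fitting failed or the template is under-determined."""


class SingularSystemError(LitterSimError):
    """A (co)kriging system is numerically singular, typically from duplicated
    data locations."""

    def __init__(self, message, duplicates=None):
        super().__init__(message)
        self.duplicates = duplicates


class SampleFileError(LitterSimError):
    """A sample file failed validation; ``rows`` lists offending line numbers."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = tuple(rows) if rows else ()


class PartitionError(LitterSimError):
    """Sector definition does not partition the grid."""
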