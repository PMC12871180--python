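"""Exception types shared across the package."""


class MorphGwrError(Exception):
    """Base class for all package errors."""


class ValidationError(MorphGwrError, ValueError):
    """Invalid argument or malformed input data."""


class CapacityError(ValidationError):
    """Requested more cells than the raster can hold."""


class DegenerateInputError(MorphGwrError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class LocalSingularityError(MorphGwrError, ValueError):
    """A local weighted design matrix is rank deficient.

    Carries the index of the offending fit location so the caller can
    report which cell / bandwidth combination failed.
    """

    def __init__(self, location_index: int, message: str | None = None):
        self.location_index = location_index
        super().__init__(
            message
            or f"rank-deficient local design at location index {location_index}; "
            "bandwidth is likely too small"
        )
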