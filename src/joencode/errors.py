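"""Exception types shared across the package."""


class JoEncodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(JoEncodeError, ValueError):
    """A protocol specification violates its invariants."""


class CalibrationRangeError(JoEncodeError, ValueError):
    """A voltage or displacement falls outside the calibration table."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class FilterDesignError(JoEncodeError, ValueError):
    """The sample rate cannot support the requested filter band."""


class WindowError(JoEncodeError, ValueError):
    """An analysis window falls outside the available data."""


class QCError(JoEncodeError, ValueError):
    """Trial quality-control contract violation (e.g. empty trace)."""


class RasterError(JoEncodeError, ValueError):
    """Raster assembly contract violation (no accepted trials, mixed stimuli)."""


class FitError(JoEncodeError, ValueError):
    """A fit was requested on data that violates its preconditions."""


class BranchError(JoEncodeError, ValueError):
    """Stair-branch extraction failed (unpaired levels, too few holds)."""
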