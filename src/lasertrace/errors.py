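"""Exception hierarchy for lasertrace."""


class LaserTraceError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(LaserTraceError):
    """Requested zig-zag geometry is infeasible (no amplitude satisfies the
    trace-length constraint inside the board)."""


class CalibrationError(LaserTraceError):
    """Pixel-to-mm calibration could not be estimated (degenerate corners)."""


class NoPatternFound(LaserTraceError):
    """Corner detection failed: no dark on-pixels, or degenerate quadrilateral."""


class TrialNotSegmentable(LaserTraceError):
    """The dot never dwells near a terminal corner long enough to place the
    start or end of the trial."""

    def __init__(self, terminus: str, message: str | None = None):
        self.terminus = terminus
        super().__init__(message or f"trial not segmentable: no dwell at {terminus!r} terminus")


class ConfigError(LaserTraceError):
    """Invalid or unknown run-configuration keys/values."""
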