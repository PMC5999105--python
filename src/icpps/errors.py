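"""Exception hierarchy for icpps.

All user-facing failures derive from :class:`IcppsError` so the CLI can
turn them into categorized exit messages instead of stack traces.
"""


class IcppsError(Exception):
    """Base class for all icpps errors."""


class ParameterError(IcppsError, ValueError):
    """An argument is outside its valid range."""


class CorrespondenceError(IcppsError, ValueError):
    """Paired point sets disagree in length."""


class DegenerateGeometryError(IcppsError, ValueError):
    """Geometry too degenerate for the requested operation (collinear
    points, coincident vertices, empty mesh, ...)."""


class InputError(IcppsError, ValueError):
    """An input point set violates a precondition (too few points,
    empty set, ...)."""


class ConfigurationError(IcppsError, ValueError):
    """Labels, regions or configuration files are missing or inconsistent."""


class SamplingError(IcppsError, ValueError):
    """A labeled region is too small to draw the requested sample."""


class GenerationError(IcppsError, ValueError):
    """Synthetic-mesh parameters cannot produce a valid labeled model."""


class StlParseError(IcppsError, ValueError):
    """Malformed STL input.

    Attributes
    ----------
    byte_offset : int or None
        Position in the file at which the structure became inconsistent,
        when it can be determined.
    """

    def __init__(self, message: str, byte_offset: int | None = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
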