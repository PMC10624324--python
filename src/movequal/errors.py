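"""Exception hierarchy shared across the pipeline stages."""


class MovequalError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MovequalError):
    """A pose frame document does not follow the expected JSON dialect."""


class EmptyFrameError(MovequalError):
    """A frame document contains no detected person."""


class InsufficientDataError(MovequalError):
    """Fewer usable frames than the minimum a computation needs."""


class DegenerateGeometryError(MovequalError):
    """A geometric primitive received coincident or zero-length inputs."""


class EmptySignalError(MovequalError):
    """A signal has no valid frame to compute from."""


class MissingRatingsError(MovequalError):
    """A rating table is incomplete where completeness is required."""


class DegenerateLabelsError(MovequalError):
    """Training labels contain a single class."""


class ConfigurationError(MovequalError):
    """An invalid or inconsistent configuration value."""


class GatedParameterError(MovequalError):
    """Classification requested for a parameter the agreement gate rejected."""
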