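"""Exception hierarchy for the connectivity pipeline."""


class LynxlinkError(Exception):
    """Base class for all package errors."""


class GridFormatError(LynxlinkError):
    """A raster file could not be parsed (malformed header, bad dialect)."""


class UnsupportedGeometryError(LynxlinkError):
    """Raster geometry outside the supported model (e.g. non-square pixels)."""


class ParameterError(LynxlinkError):
    """An operation parameter is outside its documented domain."""


class EmptyRegionError(LynxlinkError):
    """A statistic was requested over zero eligible pixels."""


class DegenerateGeometryError(LynxlinkError):
    """Too few / collinear points for a polygon operation."""


class ConfigError(LynxlinkError):
    """Pipeline configuration is invalid or inconsistent."""


class GenerationError(LynxlinkError):
    """The synthetic-landscape generator could not satisfy its constraints."""


class InvalidCutError(LynxlinkError):
    """A region-splitting polyline did not yield exactly two connected parts."""


class MissingPrerequisiteError(LynxlinkError):
    """A pipeline stage was invoked before the stage outputs it consumes exist."""
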