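"""Exception hierarchy for gaitmono."""


class GaitError(Exception):
    """Base class for all gaitmono errors."""


class ParseError(GaitError):
    """A pose or feature file could not be parsed."""


class SkeletonError(GaitError):
    """Required joints are missing from a pose sequence."""


class InsufficientDataError(GaitError):
    """Not enough frames/events to compute the requested quantity."""


class ParameterError(GaitError):
    """An operation parameter is out of its valid range."""


class DegenerateGeometryError(GaitError):
    """A joint configuration has zero-length limb vectors."""


class ConfigurationError(GaitError):
    """Generator or pipeline configuration is internally inconsistent."""
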