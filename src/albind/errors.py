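"""Exception hierarchy shared across the package."""


class AlbindError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(AlbindError):
    """Malformed delimited-text spectrum (names the offending line)."""


class InvariantError(AlbindError, ValueError):
    """A domain-type invariant is violated."""


class GridMismatchError(AlbindError):
    """Two spectra do not share an identical axis grid."""


class WindowRangeError(AlbindError):
    """An integration/sampling window falls outside the axis range."""


class DataError(AlbindError):
    """Measured values are unusable (e.g. non-positive intensities)."""


class FitError(AlbindError):
    """A least-squares fit failed or the model is unidentifiable."""


class ClassificationError(AlbindError):
    """Mechanism classification is not possible with the given input."""


class DetectionError(AlbindError):
    """A band maximum could not be located in its search window."""


class GenerationError(AlbindError):
    """A synthetic-data scenario violates its invariants."""


class ConfigError(AlbindError):
    """A run configuration or manifest is incomplete or inconsistent."""
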