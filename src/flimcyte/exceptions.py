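"""Exception hierarchy.

Every error raised by the package derives from :class:`FlimcyteError` so
callers (and the CLI) can catch the whole family with one clause while the
specific subclasses keep stage-level failures distinguishable.
"""


class FlimcyteError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FlimcyteError, ValueError):
    """A physical parameter is out of its valid domain (e.g. negative lifetime)."""


class LowSignalError(FlimcyteError):
    """Too few photons to attempt a fit; the pixel/decay is flagged, not fitted."""


class ConvergenceError(FlimcyteError):
    """The nonlinear fit did not converge within the iteration cap."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedRatioError(FlimcyteError, ZeroDivisionError):
    """Redox ratio requested with zero total intensity."""


class ConfigError(FlimcyteError, ValueError):
    """Invalid or inconsistent configuration."""


class DimensionError(FlimcyteError, ValueError):
    """Array shapes do not match."""


class DegenerateImageError(FlimcyteError):
    """A histogram-based threshold was asked for on a (near-)constant image."""


class EmptyEnsembleError(FlimcyteError):
    """ensemble selection called with no candidates."""


class MissingTruthError(FlimcyteError):
    """Per-image argmax voting requires a ground-truth mask that was not given."""


class UndefinedDiceError(FlimcyteError, ZeroDivisionError):
    """Dice coefficient of two empty masks is undefined."""


class PackingError(FlimcyteError):
    """Could not place the requested number of non-overlapping cells."""


class IntegrityError(FlimcyteError):
    """Duplicate (fov_id, cell_id) keys or schema violation in a feature table."""


class InsufficientDataError(FlimcyteError):
    """Not enough rows/values for the requested statistic."""


class DataError(FlimcyteError, ValueError):
    """NaN or otherwise unusable values where finite data is required."""


class FormatError(FlimcyteError, IOError):
    """File does not conform to the expected on-disk format."""


class MetadataError(FormatError):
    """Required sidecar metadata is missing or inconsistent."""
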