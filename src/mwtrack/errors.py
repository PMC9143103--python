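"""Exception hierarchy for mwtrack.

All package-specific failures derive from :class:`MwtrackError` so callers
(and the CLI exit-code mapping) can distinguish configuration problems,
data problems, and recoverable no-detection outcomes.
"""


class MwtrackError(Exception):
    """Base class for all mwtrack errors."""


class ConfigError(MwtrackError):
    """Invalid configuration: unknown taper name, bad schema, bad option."""


class InvalidGeometryError(ConfigError):
    """Array geometry violates its invariants (n < 2, non-positive diameter)."""


class InvalidMediumError(ConfigError):
    """Relative permittivity below 1 (faster-than-vacuum propagation)."""


class DataError(MwtrackError):
    """Malformed or inconsistent input data (files, spectra, traces)."""


class IncompatibleMeasurementError(DataError):
    """Two measurements do not share geometry and/or frequency grid."""


class IncompatibleInputError(DataError):
    """Trace count does not match the antenna count, or grids mismatch."""


class InsufficientChannelsError(DataError):
    """An operation needs more antenna channels than were provided."""


class UndefinedMetricError(DataError):
    """A metric is undefined for the given input (e.g. zero-energy pulse)."""


class DegenerateImageError(DataError):
    """An image with no positive content where structure was required."""


class NoDetectionError(MwtrackError):
    """No white region survived binarization; recoverable per position."""


class IncompleteRangeError(DataError):
    """A requested position label is missing from a track."""
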