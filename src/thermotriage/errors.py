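"""Exception hierarchy.

All domain errors derive from :class:`ThermoTriageError` so callers (and the
CLI) can distinguish bad input from programming bugs.
"""


class ThermoTriageError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(ThermoTriageError):
    """A file could not be parsed in the declared dialect (e.g. ragged CSV)."""


class CalibrationMissing(ThermoTriageError):
    """A 16-bit image has no JSON sidecar giving the DN-to-Celsius calibration."""


class RangeError(ThermoTriageError):
    """A temperature value is outside the plausible range for this application."""


class EncodingError(ThermoTriageError):
    """A temperature does not fit the 16-bit digital-number range at the given scale."""


class DegenerateROI(ThermoTriageError):
    """A region of interest contains no pixels at the requested resolution."""


class ShapeError(ThermoTriageError):
    """Mask and image shapes disagree."""


class InsufficientData(ThermoTriageError):
    """Too few observations for the requested fit or summary."""


class DegenerateGeometry(ThermoTriageError):
    """Calibration points carry no geometric information (e.g. all coincident)."""


class SpecError(ThermoTriageError):
    """A synthetic face specification is internally inconsistent."""
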