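"""Exception hierarchy.

All readers and numerical stages raise subclasses of :class:`UrethrakinError`
so callers (and the batch pipeline) can distinguish bad inputs from
processing failures.
"""


class UrethrakinError(Exception):
    """Base class for all package errors."""


class ArgumentError(UrethrakinError, ValueError):
    """Invalid argument value (wrong label, empty series, bad shape...)."""


class CalibrationError(UrethrakinError):
    """Pixel spacing or frame rate missing and no override supplied."""


class SchemaError(UrethrakinError):
    """Malformed annotation/config file; message names the offending field."""


class ParseError(UrethrakinError):
    """Malformed tabular file; message carries the line number."""


class LowTextureError(UrethrakinError):
    """Too few trackable features inside an ROI."""


class TrackingLossError(UrethrakinError):
    """Optical flow lost all points, or an ROI left the frame."""


class DegeneratePoseError(UrethrakinError):
    """Not enough valid correspondences to estimate a rigid pose."""


class DegenerateGeometryError(UrethrakinError):
    """Coincident landmarks or zero inter-segment distance."""


class MissingDataError(UrethrakinError):
    """Incomplete repeated-measures cells; no silent imputation is done."""
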