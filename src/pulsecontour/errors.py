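"""Exception hierarchy for pulsecontour.

All library errors derive from :class:`PulseContourError` so callers (and the
CLI) can distinguish data/processing problems from programming errors.
"""


class PulseContourError(Exception):
    """Base class for all pulsecontour errors."""


class FormatError(PulseContourError):
    """A file could not be parsed; the message carries a line number."""


class OnsetDetectionError(PulseContourError):
    """No plausible cardiac-cycle onsets could be located in a recording."""


class EnvelopeError(PulseContourError):
    """The respiratory envelope cannot be estimated or is unusable."""


class CalibrationError(PulseContourError):
    """The synthetic beat shape could not be calibrated to the requested
    morphology parameters."""


class MissingFiducialError(PulseContourError):
    """A mandatory fiducial point (A, B or E) is absent."""


class PipelineError(PulseContourError):
    """Pipeline stages were requested out of order or an upstream artifact
    is missing."""
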