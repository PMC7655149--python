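"""Exception hierarchy shared across the toolkit.

Everything derives from :class:`SRMError` so callers can catch toolkit
failures with one clause; the subclasses distinguish bad arguments, malformed
files, and inputs that are formally valid but carry no usable signal.
"""


class SRMError(Exception):
    """Base class for all srmtools errors."""


class ValidationError(SRMError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SRMError, ValueError):
    """An on-disk artefact does not match the expected layout."""


class DegenerateInputError(SRMError, ValueError):
    """Input is structurally valid but has no exploitable content
    (e.g. a zero-variance frame offered for correlation)."""


class CalibrationError(SRMError, RuntimeError):
    """A calibration step found no usable structure."""


class ClassificationError(SRMError, RuntimeError):
    """Particle classification rejected every candidate."""
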