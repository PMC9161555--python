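"""Exception hierarchy for lsmkit.

Every error raised on a documented contract violation derives from
:class:`LsmError` so callers can catch microscope-logic failures separately
from programming errors.
"""


class LsmError(Exception):
    """Base class for all lsmkit errors."""


class ConfigError(LsmError, ValueError):
    """A scan configuration violates an invariant.

    Carries the name(s) of the offending field(s) in :attr:`fields`.
    """

    def __init__(self, fields, message):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        super().__init__(f"{message} (field(s): {', '.join(self.fields)})")


class SettingsParseError(LsmError):
    """Settings XML is malformed or missing mandatory elements."""


class EmptyImageError(LsmError, ValueError):
    """An all-zero image was passed to the focus metric."""


class DegenerateSweepError(LsmError):
    """All focus measures in a sweep are equal; normalization is undefined."""


class FocusFitError(LsmError):
    """Gaussian best-focus fit failed to converge or is unreliable."""


class ResolutionUndefinedError(LsmError, ValueError):
    """No frequency component above threshold; resolution is undefined."""


class CalibrationError(LsmError):
    """Scan-axis calibration aborted (a focus sweep failed)."""


class CalibrationDomainError(LsmError, ValueError):
    """Evaluation of a calibration function outside its knot domain."""


class PhantomPackingError(LsmError):
    """Could not place the requested number of non-overlapping nuclei."""


class BufferOverrunError(LsmError):
    """Write buffer stayed above its high-water mark past the grace period.

    Signals that the disk cannot sustain the camera data rate. The
    acquisition statistics collected up to the abort are attached as
    :attr:`stats`.
    """

    def __init__(self, message, stats=None):
        super().__init__(message)
        self.stats = stats
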