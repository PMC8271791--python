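"""Exception hierarchy for the acquisition stack.

All protocol-level failures derive from :class:`NeurostimError` so callers can
catch the package's own errors without masking programming mistakes.
"""


class NeurostimError(Exception):
    """Base class for all errors raised by this package."""


class RegisterRangeError(NeurostimError, ValueError):
    """A register was assigned a value outside its encodable range."""

    def __init__(self, register: str, value, lo, hi):
        self.register = register
        self.value = value
        super().__init__(
            f"register {register!r}: value {value!r} outside valid range [{lo}, {hi}]"
        )


class CapacityError(NeurostimError, ValueError):
    """More commands than the chunk's word budget can hold."""


class ProtocolOrderError(NeurostimError, ValueError):
    """State-change command encountered after the first real-time command."""


class DecodeError(NeurostimError, ValueError):
    """Unparseable bitstream content.

    Carries the line and word offset of the offending frame so corrupted
    streams can be located.
    """

    def __init__(self, message: str, line: int | None = None, word_offset: int | None = None):
        self.line = line
        self.word_offset = word_offset
        loc = ""
        if line is not None:
            loc += f" (line {line}"
            if word_offset is not None:
                loc += f", word offset {word_offset}"
            loc += ")"
        super().__init__(message + loc)


class SchedulingError(NeurostimError, ValueError):
    """Overlapping or otherwise impossible stimulation events."""


class QuantizationError(NeurostimError, ValueError):
    """Requested amplitude is not representable by the DAC code space."""


class SequencingError(NeurostimError, ValueError):
    """Sync-queue identifiers are out of order."""


class AlignmentError(NeurostimError, ValueError):
    """Dataset and stimulation schedule do not line up."""


class FitError(NeurostimError, RuntimeError):
    """Curve fitting failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)


class ReplayBusyError(NeurostimError, RuntimeError):
    """A replay was requested while another run or replay is active."""
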