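"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage errors are handled by
click itself): :class:`InputError` and its subclasses signal problems with
the data handed to an operation, :class:`ConfigError` signals an invalid
configuration or ROI definition, and :class:`ComputationError` signals a
numerically degenerate result.
"""


class RoipulseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RoipulseError, ValueError):
    """Invalid configuration, ROI definition, or simulation parameters."""


class InputError(RoipulseError, ValueError):
    """Input data violates an operation's preconditions."""


class AlignmentError(InputError):
    """Estimate and reference series do not overlap in time."""


class SamplingRateError(InputError):
    """Sampling rate too low for the requested frequency band."""


class ComputationError(RoipulseError, RuntimeError):
    """A computation produced a degenerate or undefined result."""
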