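"""Exception hierarchy shared across the pipeline."""


class TiltpipeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TiltpipeError, ValueError):
    """A configuration value violates its constraints."""


class InvalidInputError(TiltpipeError, ValueError):
    """An input table or argument is malformed or out of domain."""


class DegenerateInputError(TiltpipeError, ValueError):
    """Input is formally valid but the statistic is undefined on it
    (zero baseline, singular scatter, zero pooled SD, ...)."""


class StateError(TiltpipeError, RuntimeError):
    """An operation was applied in an invalid order (e.g. re-normalizing
    an already ROI-normalized trace)."""


class FormatError(TiltpipeError, ValueError):
    """A file could not be parsed; message names the offending entry."""
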