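"""Exception hierarchy shared by all bcgkit modules."""


class BcgkitError(Exception):
    """Base class for all bcgkit errors."""


class ParameterError(BcgkitError, ValueError):
    """A configuration or function parameter violates its precondition."""


class InputError(BcgkitError, ValueError):
    """Input data (signals, annotation tracks, ...) is malformed."""


class FormatError(BcgkitError, ValueError):
    """An on-disk file does not conform to the expected format."""


class StateError(BcgkitError, RuntimeError):
    """An object is used before it reached the required state (e.g. untrained model)."""


class InsufficientDataError(BcgkitError, ValueError):
    """Not enough usable data to compute the requested quantity."""


class UndefinedMetricError(BcgkitError, ZeroDivisionError):
    """A metric's denominator is zero."""


class NoUsableChannelError(BcgkitError, ValueError):
    """Every channel's interval series is empty; channel selection impossible."""


class NoComparableDataError(BcgkitError, ValueError):
    """Two series share no comparison windows."""
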