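"""Exception hierarchy shared across the package."""


class LrenrichError(Exception):
    """Base class for all package errors."""


class InputError(LrenrichError, ValueError):
    """Invalid or unusable input data (empty files, empty intersections, ...)."""


class ConfigurationError(LrenrichError, ValueError):
    """Invalid configuration: unknown method names, missing mapped columns, ..."""


class RowError(LrenrichError, ValueError):
    """A specific data row could not be parsed; message names the line."""


class ConsistencyError(LrenrichError, ValueError):
    """Cross-object inconsistency, e.g. a tree whose labels do not match a matrix."""


class DegenerateConceptError(LrenrichError, ValueError):
    """A concept with no members in the universe, or equal to the universe."""
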