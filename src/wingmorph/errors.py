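"""Exception types shared across the package."""


class WingmorphError(Exception):
    """Base class for all package errors."""


class ParameterError(WingmorphError, ValueError):
    """A supplied parameter violates its documented domain."""


class DegenerateOutlineError(WingmorphError, ValueError):
    """An outline has too few distinct points, zero perimeter or zero area."""


class FormatError(WingmorphError, ValueError):
    """An input file could not be parsed as the requested format."""


class OutOfBoundsError(WingmorphError, ValueError):
    """A morphospace coordinate falls outside the theoretical grid."""
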