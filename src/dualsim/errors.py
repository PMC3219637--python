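"""Exception hierarchy shared across the package."""


class DualsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(DualsimError, ValueError):
    """An environment/tracker/parameter specification violates its invariants."""


class ParseError(DualsimError, ValueError):
    """A delimited input file could not be parsed; the message names the row."""


class CannotInterpolateError(DualsimError, ValueError):
    """Fewer than two samples: no interpolation onto a time grid is possible."""


class DegenerateRangeError(DualsimError, ValueError):
    """A constant series cannot be affinely normalized (the map is undefined)."""


class NoConvergenceError(DualsimError, RuntimeError):
    """A steady cycle was not reached within the iteration budget."""


class BracketError(DualsimError, ValueError):
    """The fitness difference does not change sign over the supplied bracket."""


class ConfigError(DualsimError, ValueError):
    """A configuration file or config object violates the published schema."""
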