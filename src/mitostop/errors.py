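"""Exception hierarchy used across the package."""


class MitostopError(Exception):
    """Base class for all package errors."""


class ParseError(MitostopError):
    """A file could not be parsed; the message names the offending line."""


class AlphabetError(MitostopError):
    """A sequence contained characters outside the expected alphabet."""


class FrameError(MitostopError):
    """A coding sequence length is not a multiple of three."""


class CoordinateError(MitostopError):
    """A coordinate operation was invalid (e.g. wrap on a linear genome)."""


class CoverageError(MitostopError):
    """A required genome position is absent from a count table."""


class UndefinedFrequencyError(MitostopError):
    """A frequency was requested at zero depth, or a score at zero on-target."""


class DesignInfeasibleError(MitostopError):
    """No TALE window placement satisfies the geometric constraints."""


class SpecError(MitostopError):
    """A synthetic-genome specification is internally inconsistent."""
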