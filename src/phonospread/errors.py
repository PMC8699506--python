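"""Exception hierarchy shared across the package."""


class PhonoSpreadError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhonoSpreadError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PhonoSpreadError, ValueError):
    """An input violates a structural invariant (empty transcription,
    decay outside [0, 1], duplicate labels, ...)."""


class ResolutionError(PhonoSpreadError, KeyError):
    """A stimulus word does not resolve to a lexicon entry or network node."""


class CapacityError(PhonoSpreadError, ValueError):
    """A generator spec asks for more distinct items than its alphabet
    and length support can host."""


class ContrastError(PhonoSpreadError, ValueError):
    """A contrast generator's parameters do not realize the requested
    contrast (e.g. p_high <= p_low)."""


class DesignError(PhonoSpreadError, ValueError):
    """An experiment design is malformed (e.g. not exactly two conditions)."""


class DegenerateDataError(PhonoSpreadError, ValueError):
    """A statistic is undefined for the given data (e.g. zero pooled
    variance with unequal means)."""
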