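"""Exception hierarchy for pilot-design calculations."""


class PilotSizeError(ValueError):
    """Base class for all pilotsize errors."""


class InvalidParameterError(PilotSizeError):
    """A statistical parameter is outside its legal range (e.g. theta not in (0,1))."""


class InvalidDesignError(PilotSizeError):
    """A study design is degenerate (e.g. fewer than 2 subjects per arm)."""


class UndefinedGainError(PilotSizeError):
    """Relative precision gain is undefined because the baseline width is zero."""


class ConfigError(PilotSizeError):
    """A study configuration failed validation; the message carries the field path."""
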