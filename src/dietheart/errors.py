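"""Exception hierarchy for the dietheart package.

Every error raised deliberately by this package derives from
:class:`DietHeartError`, so callers (and the CLI) can distinguish expected
failure modes from genuine bugs.
"""


class DietHeartError(Exception):
    """Base class for all dietheart errors."""


class ConfigError(DietHeartError, ValueError):
    """A generator or run configuration is invalid; the message names the field."""


class InputError(DietHeartError, ValueError):
    """An analysis routine received unusable input (empty group, size mismatch...)."""


class DegenerateInputError(InputError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class ParseError(DietHeartError, ValueError):
    """A cohort file could not be parsed; the message names the offending row."""
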