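"""Exception types shared across the package."""


class PorcError(Exception):
    """Base class for package-specific errors."""


class ConfigError(PorcError, ValueError):
    """A configuration field is invalid; the message names the field."""


class TraceFormatError(PorcError, ValueError):
    """An EMG trace violates its format contract (e.g. non-increasing times)."""


class MissingScoreError(PorcError, ValueError):
    """A score required to route a patient through a tree is absent."""


class SpecValidationError(PorcError, ValueError):
    """A decision-tree specification failed structural validation."""


class UndefinedMarginError(PorcError, ValueError):
    """A 2x2 table margin is empty, so the requested proportion is undefined."""
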