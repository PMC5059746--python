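"""Exception hierarchy shared by all strata-viper modules."""


class StrataViperError(Exception):
    """Base class for all package errors."""


class ConfigError(StrataViperError):
    """A configuration value violates its invariant; names the offending field."""


class InputError(StrataViperError):
    """Malformed or inconsistent user input."""


class ParseError(InputError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EstimationError(StrataViperError):
    """An estimator could not produce a result (e.g. no main k-mer peak)."""


class NormalizationError(StrataViperError):
    """A normalizing constant is zero or unavailable."""


class SaturationError(StrataViperError):
    """A distance correction is undefined (substitution saturation)."""
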