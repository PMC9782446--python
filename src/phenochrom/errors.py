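"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation, parse, configuration and
unsupported-feature errors map to exit code 2; numerical failures map to 3.
"""


class PhenochromError(Exception):
    """Base class for all package errors."""


class ValidationError(PhenochromError):
    """Input data violates a documented invariant or precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending section."""


class ConfigurationError(ValidationError):
    """A required piece of configuration (basis, overlap, fragment) is missing."""


class UnsupportedFeatureError(ValidationError):
    """Input requests a feature outside the supported scope (e.g. g shells)."""


class AmbiguityError(ValidationError):
    """A quantity (e.g. the HOMO) cannot be assigned unambiguously."""


class NumericalError(PhenochromError):
    """A numerical procedure failed (ill-conditioned matrix, no convergence)."""
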