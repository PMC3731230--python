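"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, I/O failures to exit code 3.
"""


class HaplogwasError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HaplogwasError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class BiallelismError(ValidationError):
    """A site carries more than two observed allele states."""


class ParameterError(ValidationError, ValueError):
    """A parameter is outside its documented domain."""
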