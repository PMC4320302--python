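"""Exception hierarchy shared across the package.

Domain errors (bad arguments, violated preconditions) are ``ValueError``
subclasses so they behave naturally with numpy/scipy call sites; the CLI
maps each class onto its documented exit code.
"""


class DomainError(ValueError):
    """A precondition on an operation's arguments was violated."""


class ConfigurationError(DomainError):
    """A required configuration value is missing or inconsistent (exit code 2)."""


class DataFormatError(IOError):
    """An input file is missing, truncated, or not valid imzML (exit code 3)."""


class NumericalError(ArithmeticError):
    """A numerical routine failed to converge or produced non-finite output (exit code 4)."""
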