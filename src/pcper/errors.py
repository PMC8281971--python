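"""Exception taxonomy shared across the package.

Validation failures derive from :class:`ValueError` so they behave naturally
in Python code; numerical breakdowns derive from :class:`RuntimeError`.
The CLI maps validation errors to exit code 2 and numerical ones to 3.
"""


class PcperError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PcperError, ValueError):
    """Malformed or inconsistent data (shapes, finiteness, label coverage)."""


class InvalidParameterError(PcperError, ValueError):
    """A hyper-parameter outside its valid range."""


class ConfigurationError(PcperError, ValueError):
    """An unusable kernel or run configuration (e.g. unknown kernel name)."""


class ParseError(PcperError, ValueError):
    """A text input file that cannot be parsed; carries the offending row."""


class NumericalError(PcperError, RuntimeError):
    """A linear solve or objective evaluation that broke down numerically."""
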