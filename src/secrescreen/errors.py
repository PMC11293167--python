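"""Exception hierarchy.

Data errors (bad input content) and config errors (bad parameters) are kept
distinct so the CLI can map them onto exit codes 1 and 2 respectively.
"""


class SecreScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(SecreScreenError):
    """Invalid parameter values or pipeline configuration."""


class DataError(SecreScreenError):
    """Invalid input data content (negative abundances, empty library...)."""


class FormatError(DataError):
    """A file does not conform to its expected dialect."""
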