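"""Exception hierarchy.

Configuration problems (bad parameters, impossible settings) and data
problems (malformed or inconsistent inputs) are distinguished so the CLI
can map them onto distinct exit codes (2 and 3 respectively).
"""


class PaleodupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PaleodupError):
    """Invalid parameter or configuration value."""


class DataError(PaleodupError):
    """Malformed, missing or inconsistent input data."""
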