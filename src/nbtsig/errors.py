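"""Exception hierarchy mapped to CLI exit codes."""


class NbtsigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NbtsigError):
    """Invalid configuration (exit code 2)."""

    exit_code = 2


class DataError(NbtsigError):
    """Malformed or inconsistent input data (exit code 3)."""

    exit_code = 3


class NumericalError(NbtsigError):
    """A numerical procedure failed to produce a usable result (exit code 4)."""

    exit_code = 4
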