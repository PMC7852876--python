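"""Exception hierarchy shared across the package (and mapped to CLI exit codes)."""


class SiblineError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(SiblineError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class InputError(SiblineError):
    """Missing or malformed input data."""

    exit_code = 3


class EstimationError(SiblineError):
    """The mutation-rate estimate cannot be computed."""

    exit_code = 4
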