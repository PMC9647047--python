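"""Exception hierarchy; the CLI maps these onto exit codes."""


class PairsigError(Exception):
    """Base class for all package errors."""


class InputError(PairsigError):
    """Invalid user-supplied data or arguments (CLI exit code 2)."""


class ConfigError(InputError):
    """Invalid configuration values."""


class FormatError(InputError):
    """A file exists but does not parse into the expected structure."""


class StageAbortError(PairsigError):
    """A pipeline stage produced an empty/degenerate result (CLI exit code 3)."""
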