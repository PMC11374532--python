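"""Exception hierarchy shared across the pipeline stages."""


class VdegkitError(Exception):
    """Base class for all package errors."""


class ConfigError(VdegkitError):
    """Invalid configuration or parameters."""


class DataError(VdegkitError):
    """Malformed or inconsistent input data."""


class StageError(VdegkitError):
    """A pipeline stage failed mid-run."""
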