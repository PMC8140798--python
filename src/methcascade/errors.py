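"""Exception hierarchy shared across the package.

CLI exit-code mapping: ConfigError -> 2, DataError (and subclasses) -> 3.
"""


class MethcascadeError(Exception):
    """Base class for all package errors."""


class ConfigError(MethcascadeError):
    """Invalid configuration value or file."""


class DataError(MethcascadeError):
    """Invalid or inconsistent input data."""


class ManifestError(DataError):
    """Malformed probe manifest (duplicate ids, unknown categories, ...)."""


class EmptyStageError(DataError):
    """A cascade stage produced an empty probe set."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} retained no probes; pipeline stopped")
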