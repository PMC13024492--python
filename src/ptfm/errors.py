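"""Exception hierarchy shared across the package."""


class PTFMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PTFMError, ValueError):
    """A device/model/run configuration is incomplete or inconsistent."""


class DomainError(PTFMError, ValueError):
    """An argument lies outside the physically or mathematically valid domain."""


class DataError(PTFMError, ValueError):
    """A dataset or manifest is malformed, empty, or inconsistent."""


class TrainingError(PTFMError, RuntimeError):
    """Training failed (e.g. a non-finite loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class ValidityWarning(UserWarning):
    """A model assumption (e.g. thin-load limit) is being stretched, not violated."""
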