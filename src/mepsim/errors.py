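"""Structured exception types shared across the package."""


class MepsimError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MepsimError):
    """A model specification violates its invariants (e.g. a non-PSD covariance)."""


class DomainError(MepsimError):
    """An input lies outside the mathematical domain of an operation."""


class SchemaError(MepsimError):
    """A design matrix does not match the column layout a fitted model expects."""


class CollinearityError(MepsimError):
    """A design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConfigError(MepsimError):
    """A run configuration file is invalid."""

    def __init__(self, message, keys=None):
        super().__init__(message)
        self.keys = list(keys) if keys is not None else []


class TrainingDivergedError(MepsimError):
    """Network training produced a non-finite loss."""

    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch
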