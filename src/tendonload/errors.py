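"""Exception hierarchy for the tendonload package."""


class TendonLoadError(Exception):
    """Base class for all tendonload errors."""


class FormatError(TendonLoadError):
    """A file does not conform to the documented dialect."""


class IntegrityError(TendonLoadError):
    """Data violates a structural invariant (ordering, identity, duplication)."""


class EmptyInputError(TendonLoadError):
    """An input that must contain data is empty."""


class DomainError(TendonLoadError, ValueError):
    """A parameter is outside its mathematical domain."""


class NumericError(TendonLoadError, ValueError):
    """Non-finite values where finite numbers are required."""


class ConfigError(TendonLoadError):
    """A configuration is internally inconsistent or infeasible."""


class DependencyError(TendonLoadError):
    """A pipeline stage was invoked before the stage it depends on."""
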