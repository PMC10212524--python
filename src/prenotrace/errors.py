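"""Exception hierarchy shared across the package."""


class PrenotraceError(Exception):
    """Base class for package-specific errors."""


class DomainError(PrenotraceError, ValueError):
    """A value violates a mathematical precondition (e.g. probability outside [0, 1])."""


class ContractViolation(PrenotraceError, ValueError):
    """Mismatched dimensions or inconsistent objects passed between operations."""


class DataError(PrenotraceError, ValueError):
    """Input data cannot be used (malformed file, empty spectrum, off-model support)."""


class ConfigurationError(PrenotraceError, ValueError):
    """Unknown preset, adduct, or invalid run configuration."""


class AdductMismatchError(DataError):
    """No peak in the list could be assigned to the expected envelope grid."""
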