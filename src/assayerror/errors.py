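"""Exception hierarchy shared across the package."""


class AssayErrorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AssayErrorError):
    """A user-supplied configuration value or column mapping is invalid."""


class IntegrityError(AssayErrorError):
    """A dataset violates a structural invariant (duplicates, n < 2, ...)."""


class DegenerateDesignError(AssayErrorError):
    """A regression design matrix is singular or under-determined."""


class UsageError(AssayErrorError):
    """An operation was called with arguments outside its domain."""
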