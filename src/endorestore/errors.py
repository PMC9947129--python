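"""Exception hierarchy shared across the package."""


class EndoRestoreError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(EndoRestoreError, ValueError):
    """Raised when image/array shapes violate an operation's contract."""


class ParameterError(EndoRestoreError, ValueError):
    """Raised when a scalar or enum parameter is outside its valid domain."""


class ConfigurationError(EndoRestoreError, ValueError):
    """Raised when a configuration object is internally inconsistent
    (e.g. fine-tuning requested before coarse training)."""
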