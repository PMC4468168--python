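"""Exception types shared across the package."""


class ThermotolError(Exception):
    """Base class for package errors."""


class ConfigError(ThermotolError, ValueError):
    """Invalid configuration or generator specification."""


class FittingError(ThermotolError, RuntimeError):
    """Model fitting failed (non-convergence or separation)."""
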