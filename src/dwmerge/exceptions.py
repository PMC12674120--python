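"""Exception types shared across the package."""


class DwmergeError(Exception):
    """Base class for all package errors."""


class SchemaError(DwmergeError):
    """A required column or config field is missing or malformed."""


class ValidationError(DwmergeError):
    """Data violates a table invariant (bad sigma, duplicate observation...)."""


class GraphError(DwmergeError):
    """Dataset graph is not a single-parent DAG or references missing data."""


class ConfigError(DwmergeError):
    """Run configuration is invalid."""


class VIError(DwmergeError):
    """Variational optimization failed (non-finite objective, etc.)."""
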