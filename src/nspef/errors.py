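"""Exception hierarchy shared across the pipeline.

ValidationError signals a malformed value or record (CLI exit code 2);
ConfigurationError signals missing or inconsistent configuration, e.g. a
flow-chamber pulse count requested without flow parameters (exit code 3).
"""


class NspefError(Exception):
    """Base class for all package errors."""


class ValidationError(NspefError, ValueError):
    """Invalid input value, shape, or record."""


class ConfigurationError(NspefError, RuntimeError):
    """Missing or inconsistent configuration."""
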