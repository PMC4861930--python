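"""Exception hierarchy for the wsppq pipeline.

Every error raised deliberately by the package derives from :class:`WsppError`
so callers can catch pipeline failures without masking programming errors.
"""


class WsppError(Exception):
    """Base class for all wsppq errors."""


class FormatError(WsppError, ValueError):
    """A file does not conform to its declared format (bad header, bad field)."""


class ValidationError(WsppError, ValueError):
    """Parsed data violates an invariant (duplicate ids, negative intensity)."""


class ConfigError(WsppError, ValueError):
    """A run configuration is internally inconsistent."""


class EmptyInputError(WsppError, ValueError):
    """An operation received no usable records (e.g. all spectra dropped)."""


class EstimationError(WsppError, RuntimeError):
    """A variance component or noise scale could not be estimated."""
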