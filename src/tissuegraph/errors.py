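"""Exception hierarchy.

All package errors derive from :class:`TissueGraphError` so callers can catch
one base class at pipeline boundaries.
"""


class TissueGraphError(Exception):
    """Base class for all tissuegraph errors."""


class FormatError(TissueGraphError):
    """Input file content does not match the expected format."""


class ValidationError(TissueGraphError):
    """Data violates an invariant (duplicate labels, missing attributes, ...)."""


class ConfigError(TissueGraphError):
    """Invalid or inconsistent run parameters."""


class SerializationError(TissueGraphError):
    """An object cannot be written in the requested on-disk format."""


class GenerationError(TissueGraphError):
    """Synthetic tissue generation failed (e.g. packing constraints)."""
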