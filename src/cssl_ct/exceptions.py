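"""Exception taxonomy shared across the package."""


class CSSLError(Exception):
    """Base class for package errors."""


class ConfigurationError(CSSLError, ValueError):
    """Invalid or inconsistent configuration values."""


class ShapeError(CSSLError, ValueError):
    """Array shapes incompatible with the requested operation."""


class InvalidInputError(CSSLError, ValueError):
    """Input data violates a precondition (non-finite pixels, empty sets...)."""


class DegenerateMaskError(CSSLError, ValueError):
    """A masking ratio that leaves zero masked or zero visible patches."""


class GenerationError(CSSLError, RuntimeError):
    """Procedural phantom generation could not satisfy geometric constraints."""


class BufferStateError(CSSLError, RuntimeError):
    """Memory-buffer operation on an empty or incompatible buffer."""


class CorruptArchiveError(CSSLError, IOError):
    """A buffer or checkpoint archive failed to load cleanly."""
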