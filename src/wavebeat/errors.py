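"""Exception types shared across the package."""


class WavebeatError(Exception):
    """Base class for package errors."""


class FormatError(WavebeatError):
    """A file is missing, not a recognized container, or structurally broken."""


class DataError(WavebeatError):
    """A file parsed but its payload is unusable (non-numeric signal, ...)."""


class VocabularyError(WavebeatError):
    """A rhythm label is outside the known 9-class vocabulary."""


class CapabilityError(WavebeatError):
    """A requested rhythm class is not supported by the generator."""


class SchemaError(WavebeatError):
    """Feature schemas of two matrices do not line up."""
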