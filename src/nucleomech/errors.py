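"""Exception hierarchy shared by all assay modules."""


class NucleomechError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NucleomechError, ValueError):
    """Invalid parameter or malformed in-memory data."""


class MetadataError(NucleomechError):
    """Required image metadata missing or inconsistent with pixel data."""


class InsufficientSignalError(NucleomechError):
    """Not enough photons / samples / pixels to compute the requested quantity."""


class NonIdentifiableError(NucleomechError):
    """The model parameter cannot be identified from the data provided."""


class DegenerateFitError(NucleomechError):
    """The data admit no meaningful fit (e.g. zero spread)."""


class UndefinedRatioError(NucleomechError):
    """A ratio whose denominator is zero or non-positive."""
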