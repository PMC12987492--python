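"""Exception hierarchy for tsscall."""


class TsscallError(Exception):
    """Base class for all tsscall errors."""


class ParseError(TsscallError, ValueError):
    """A coverage or annotation file could not be parsed."""


class BoundsError(TsscallError, ValueError):
    """A genomic position lies outside the declared replicon length."""


class NormalizationError(TsscallError, ValueError):
    """A library is degenerate for the requested normalization stage."""


class ConfigurationError(TsscallError, ValueError):
    """Parameters or experiment layout are inconsistent."""


class ValidationError(TsscallError, ValueError):
    """A synthetic experiment specification is infeasible."""


class DegenerateWindowError(TsscallError, ValueError):
    """A coverage window carries no mass and defines no distribution."""
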