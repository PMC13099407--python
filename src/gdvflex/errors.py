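"""Exception hierarchy used across the package."""


class GdvflexError(Exception):
    """Base class for all gdvflex errors."""


class StructureFormatError(GdvflexError, ValueError):
    """Input file could not be parsed as a structural model."""


class ModelNotFoundError(GdvflexError, LookupError):
    """Requested model number is absent from a multi-model file."""


class DegenerateInputError(GdvflexError, ValueError):
    """Input is too small or empty for the requested operation."""


class AlignmentError(GdvflexError, ValueError):
    """Per-atom values or rosters do not line up."""


class ParameterError(GdvflexError, ValueError):
    """A parameter is outside its admissible range."""


class DomainError(GdvflexError, ValueError):
    """A value is outside the mathematical domain of a transform."""
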