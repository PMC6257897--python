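"""Exception hierarchy for the leukocount pipeline."""


class LeukocountError(Exception):
    """Base class for all package-specific errors."""


class DecodeError(LeukocountError):
    """Image file could not be read or decoded."""


class UnsupportedImageError(LeukocountError):
    """Image has an unsupported layout (e.g. single-channel grayscale)."""


class ColorSpaceError(LeukocountError):
    """Operation applied to an image in the wrong color space."""


class InsufficientDataError(LeukocountError):
    """Not enough observations to compute the requested quantity."""


class InvalidParameterError(LeukocountError):
    """Parameter outside its valid range."""


class DegenerateAnnulusError(LeukocountError):
    """No usable peri-nuclear pixels remain for cytoplasm sampling."""


class InvalidRecipeError(LeukocountError):
    """Synthetic smear recipe violates a geometric constraint."""


class PlacementError(LeukocountError):
    """Rejection sampling failed to place all requested cells."""


class UndefinedCorrelationError(LeukocountError):
    """Pearson correlation undefined (constant vector, non-identical pair)."""
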