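"""Exception hierarchy for the IHC scoring pipeline."""


class IHCScoreError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IHCScoreError):
    """Input image is not 3-channel RGB or otherwise malformed."""


class ParameterError(IHCScoreError):
    """A configuration parameter is out of its valid range."""


class DimensionError(IHCScoreError):
    """Array shapes are inconsistent."""


class DomainError(IHCScoreError):
    """Values outside the mathematical domain of an operation."""


class DegenerateImageError(IHCScoreError):
    """Image has fewer than two distinct stain directions."""


class SingularMatrixError(IHCScoreError):
    """Color-vector matrix is rank deficient."""


class ControlOrderError(IHCScoreError):
    """Control images are inconsistent with their designation
    (the high-score control does not exceed the low-score control)."""


class InsufficientDataError(IHCScoreError):
    """Too few points to fit the requested model."""
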