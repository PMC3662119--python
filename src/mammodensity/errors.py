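"""Exception hierarchy shared across the package."""


class MammoDensityError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(MammoDensityError):
    """A required header element is missing or malformed."""


class FormatError(MammoDensityError):
    """The input file cannot be parsed as a supported image format."""


class UnsupportedViewError(MammoDensityError):
    """The view position is not MLO (craniocaudal views are not handled)."""


class EmptyImageError(MammoDensityError):
    """No foreground component could be found in the image."""


class DegenerateMaskError(MammoDensityError):
    """A morphological operation produced an empty mask."""


class DegenerateHistogramError(MammoDensityError):
    """The histogram has fewer than two occupied gray levels."""


class InfeasiblePhantomError(MammoDensityError):
    """The phantom specification cannot be realized as pixels."""


class UndefinedStatisticError(MammoDensityError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
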