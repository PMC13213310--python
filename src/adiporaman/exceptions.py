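"""Exception hierarchy for the adiporaman pipeline."""


class AdipoRamanError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(AdipoRamanError):
    """Raised for map geometries with non-positive step or misaligned extents."""


class EmptyRegionError(AdipoRamanError):
    """Raised when a spectral region does not intersect the wavenumber axis."""


class ExtrapolationError(AdipoRamanError):
    """Raised when a target axis extends beyond a source axis span."""


class SpectralFormatError(AdipoRamanError):
    """Raised for malformed spectral-matrix or metadata files."""


class DegenerateSpectrumError(AdipoRamanError):
    """Raised for zero-variance spectra that cannot be SNV-normalized."""


class BaselineFitError(AdipoRamanError):
    """Raised when the polynomial baseline fit is ill-conditioned."""


class RankError(AdipoRamanError):
    """Raised when more PCA components are requested than the data rank supports."""


class CollinearityError(AdipoRamanError):
    """Raised when the EMSC design matrix is rank deficient."""


class DegenerateFitError(AdipoRamanError):
    """Raised when the EMSC reference coefficient is below the b_min guard."""


class LabelError(AdipoRamanError):
    """Raised for single-class label vectors where a classifier needs two classes."""


class StratificationError(AdipoRamanError):
    """Raised when a class has fewer members than the number of CV folds."""


class UndefinedSilhouetteError(AdipoRamanError):
    """Raised when silhouette is undefined (single label or singleton cluster)."""


class ParameterError(AdipoRamanError):
    """Raised for invalid user-supplied parameters."""
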