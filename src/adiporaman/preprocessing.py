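"""Per-spectrum preprocessing chain for Raman maps.

Four steps, applied independently to each spectrum in this order:

1. iterative polynomial baseline correction (min-clipping "ModPoly" style),
2. standard normal variate (SNV) normalization,
3. Savitzky-Golay smoothing (polynomial order 2),
4. shift back to zero minimum intensity.

Each step is available both as a plain function and as a scikit-learn
transformer; :class:`RamanPreprocessor` composes all four and operates on
raw ``(n_spectra, n_channels)`` arrays or :class:`~adiporaman.dataset.SpectralDataset`
objects via :func:`preprocess_dataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset
from .exceptions import BaselineFitError, DegenerateSpectrumError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the four-step chain.

    baseline_order
        Degree of the baseline polynomial. The fit is iterative: after each
        least-squares fit the spectrum is clipped to ``min(spectrum, fit)`` so
        that sharp Raman bands are excluded from the broad-background estimate.
    savgol_window
        Odd window length in channels; 11 by default (about half a typical
        condensed-phase band FWHM at 1 cm^-1 sampling).
    snv_ddof
        Delta degrees of freedom of the SNV standard deviation; 1 (sample sd)
        is the conventional SNV definition.
    """

    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    savgol_window: int = 11
    savgol_polyorder: int = 2
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.baseline_order < 0 or self.baseline_max_iter < 1:
            raise ParameterError("baseline_order >= 0 and baseline_max_iter >= 1 required")
        if self.savgol_window < 5 or self.savgol_window % 2 == 0:
            raise ParameterError(f"savgol_window must be odd and >= 5, got {self.savgol_window}")
        if self.savgol_polyorder >= self.savgol_window:
            raise ParameterError("savgol_polyorder must be < savgol_window")
        if self.snv_ddof not in (0, 1):
            raise ParameterError("snv_ddof must be 0 or 1")


def baseline_correct(
    spectrum: np.ndarray,
    axis: np.ndarray,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative min-clipping polynomial baseline correction.

    Fits an order-``order`` polynomial to the working spectrum, replaces the
    working spectrum with the pointwise minimum of itself and the fit, and
    repeats until the relative change of the fitted baseline drops below
    ``tol`` or ``max_iter`` is reached.  Peaks bias the fit only upward, so
    the clipping converges onto the broad background under the bands.

    Returns ``(spectrum - baseline, baseline)``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if order >= spectrum.size:
        raise BaselineFitError(
            f"baseline order {order} too high for {spectrum.size} channels"
        )
    # Map the axis to [-1, 1] so the Vandermonde basis stays well conditioned.
    x = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
    work = spectrum.copy()
    baseline = np.zeros_like(work)
    scale = max(np.ptp(spectrum), np.abs(spectrum).max(), 1e-300)
    for _ in range(max_iter):
        try:
            coeffs = np.polynomial.polynomial.polyfit(x, work, order)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise BaselineFitError(f"baseline polynomial fit failed: {exc}") from exc
        new_baseline = np.polynomial.polynomial.polyval(x, coeffs)
        change = np.max(np.abs(new_baseline - baseline)) / scale
        baseline = new_baseline
        work = np.minimum(work, baseline)
        if change < tol:
            break
    return spectrum - baseline, baseline


def snv_normalize(spectrum: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit-sd scaling.

    Spectra whose standard deviation is zero, or negligible relative to their
    mean level (flat up to floating-point residue, e.g. a constant spectrum
    after baseline subtraction), are rejected as degenerate.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    sd = spectrum.std(ddof=ddof)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(spectrum.mean())):
        raise DegenerateSpectrumError("zero-variance spectrum cannot be SNV normalized")
    return (spectrum - spectrum.mean()) / sd


def savgol_smooth(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing; edges use polynomial extrapolation."""
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ParameterError(f"savgol window must be odd, got {window}")
    if polyorder >= window or window > spectrum.size:
        raise ParameterError(
            f"need polyorder < window <= n_channels, got ({polyorder}, {window}, {spectrum.size})"
        )
    return savgol_filter(spectrum, window_length=window, polyorder=polyorder, mode="interp")


def zero_offset(spectrum: np.ndarray) -> np.ndarray:
    """Shift a spectrum so its minimum is exactly zero."""
    spectrum = np.asarray(spectrum, dtype=float)
    return spectrum - spectrum.min()


class RamanPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless four-step preprocessing transformer.

    Parameters mirror :class:`PreprocessConfig`.  ``fit`` only records the
    wavenumber axis (needed for the baseline basis); ``transform`` applies
    baseline correction, SNV, Savitzky-Golay smoothing and the zero shift
    independently to every row.
    """

    def __init__(
        self,
        baseline_order: int = 5,
        baseline_max_iter: int = 100,
        baseline_tol: float = 1e-6,
        savgol_window: int = 11,
        savgol_polyorder: int = 2,
        snv_ddof: int = 1,
    ) -> None:
        self.baseline_order = baseline_order
        self.baseline_max_iter = baseline_max_iter
        self.baseline_tol = baseline_tol
        self.savgol_window = savgol_window
        self.savgol_polyorder = savgol_polyorder
        self.snv_ddof = snv_ddof

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            baseline_order=self.baseline_order,
            baseline_max_iter=self.baseline_max_iter,
            baseline_tol=self.baseline_tol,
            savgol_window=self.savgol_window,
            savgol_polyorder=self.savgol_polyorder,
            snv_ddof=self.snv_ddof,
        )

    def fit(self, X, y=None, axis: np.ndarray | None = None):
        X = check_array(X)
        cfg = self._config()
        if cfg.baseline_order >= X.shape[1]:
            raise ParameterError("baseline_order must be < number of channels")
        self.axis_ = (
            np.asarray(axis, dtype=float) if axis is not None else np.arange(X.shape[1], dtype=float) + 1.0
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, spectrum_ids=None) -> np.ndarray:
        check_is_fitted(self, "axis_")
        X = check_array(X)
        cfg = self._config()
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            sid = spectrum_ids[i] if spectrum_ids is not None else f"row {i}"
            try:
                corrected, _ = baseline_correct(
                    row, self.axis_, cfg.baseline_order, cfg.baseline_max_iter, cfg.baseline_tol
                )
                corrected = snv_normalize(corrected, cfg.snv_ddof)
                corrected = savgol_smooth(corrected, cfg.savgol_window, cfg.savgol_polyorder)
                out[i] = zero_offset(corrected)
            except (DegenerateSpectrumError, BaselineFitError, ParameterError) as exc:
                raise type(exc)(f"spectrum {sid}: {exc}") from exc
        return out


def preprocess_dataset(ds: SpectralDataset, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply the full four-step chain to every spectrum of a dataset."""
    cfg = config or PreprocessConfig()
    pre = RamanPreprocessor(**cfg.__dict__)
    pre.fit(ds.matrix, axis=ds.axis)
    out = pre.transform(ds.matrix, spectrum_ids=ds.meta["spectrum_id"].tolist())
    logger.info(
        "preprocessed %d spectra (baseline order %d, SavGol %d/%d, SNV ddof %d)",
        ds.n_spectra, cfg.baseline_order, cfg.savgol_window, cfg.savgol_polyorder, cfg.snv_ddof,
    )
    return ds.with_matrix(out)
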