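"""Extended multiplicative scatter correction with PCA-derived interference.

Resonance Raman scattering of carotenoids (532 nm excitation sits close to
their electronic absorption) makes the 1004 / 1155 / 1520 cm^-1 bands vary in
intensity from spectrum to spectrum in a way ordinary normalization cannot
remove.  The correction implemented here models each spectrum ``s`` as

    s = a + sum_{i=1..p} c_i * t^i  +  b * r  +  sum_j d_j * g_j  +  e

where ``r`` is the reference spectrum (the dataset mean), ``t`` is the
wavenumber axis affinely mapped to [-1, 1], and the ``g_j`` are leading PCA
loadings of the preprocessed dataset, which carry the dominant
carotenoid-intensity variation.  Ordinary least squares gives the
coefficients; the corrected spectrum is

    (s - a - sum c_i t^i - sum d_j g_j) / b

so baseline and interference contributions are neutralized and the
multiplicative scatter factor is divided out.

:class:`EMSCCorrector` wraps the whole stage as a scikit-learn transformer:
``fit`` learns the reference and the interference basis from a dataset,
``transform`` corrects spectra against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset
from .exceptions import CollinearityError, DegenerateFitError, ParameterError, RankError

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_THRESHOLD = 0.96
DEFAULT_MAX_COMPONENTS = 10
DEFAULT_POLY_ORDER = 4
DEFAULT_B_MIN = 1e-6


@dataclass(frozen=True)
class InterferenceBasis:
    """Orthonormal PCA loading spectra used as EMSC interference columns."""

    components: np.ndarray  # (k, n_channels)
    explained_variance_ratio: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        comps = np.atleast_2d(np.asarray(self.components, dtype=float))
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if comps.shape[0] != evr.size:
            raise ParameterError("one explained-variance ratio per component required")
        gram = comps @ comps.T
        if not np.allclose(gram, np.eye(comps.shape[0]), atol=1e-8):
            raise ParameterError("interference components must be orthonormal")
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ParameterError("explained variance ratios must be non-increasing, sum <= 1")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "explained_variance_ratio", evr)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def extract_interference_components(
    X: np.ndarray | SpectralDataset,
    n_components: int | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> InterferenceBasis:
    """Mean-centered PCA of the preprocessed dataset.

    With ``n_components`` set, that many leading loadings are returned;
    otherwise the smallest k whose cumulative explained variance reaches
    ``variance_threshold`` (capped at ``max_components``).  A fixed
    ``n_components=5`` reproduces the published configuration, where five
    components explained more than 96% of the variance.
    """
    matrix = X.matrix if isinstance(X, SpectralDataset) else np.asarray(X, dtype=float)
    n = matrix.shape[0]
    if n_components is not None and n < max(n_components + 1, 2):
        raise RankError(f"{n} spectra cannot support {n_components} components")
    rank = np.linalg.matrix_rank(matrix - matrix.mean(axis=0))
    if n_components is not None and n_components > rank:
        raise RankError(f"requested {n_components} components but data rank is {rank}")
    k_fit = n_components if n_components is not None else int(min(max_components, rank, n - 1))
    k_fit = max(k_fit, 1)
    pca = PCA(n_components=k_fit, svd_solver="full")
    pca.fit(matrix)
    comps = pca.components_
    evr = pca.explained_variance_ratio_
    if n_components is None:
        cumulative = np.cumsum(evr)
        k = int(np.searchsorted(cumulative, variance_threshold) + 1)
        k = min(k, k_fit)
        comps, evr = comps[:k], evr[:k]
    logger.info(
        "interference basis: %d components, cumulative explained variance %.4f",
        comps.shape[0], float(evr.sum()),
    )
    return InterferenceBasis(comps, evr)


def _scaled_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    return 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0


@dataclass(frozen=True)
class EMSCModel:
    """Reference spectrum + polynomial basis + interference basis."""

    reference: np.ndarray
    poly_order: int
    interference: InterferenceBasis
    axis: np.ndarray
    b_min: float = DEFAULT_B_MIN
    design: np.ndarray = field(init=False, repr=False)
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if not (ref.size == axis.size == self.interference.components.shape[1]):
            raise ParameterError("reference, axis and interference lengths must agree")
        t = _scaled_axis(axis)
        poly = np.vander(t, self.poly_order + 1, increasing=True)  # 1, t, ..., t^p
        design = np.column_stack([poly, ref, self.interference.components.T])
        names = (
            ["constant"]
            + [f"poly_{i}" for i in range(1, self.poly_order + 1)]
            + ["reference"]
            + [f"interference_{j + 1}" for j in range(self.interference.n_components)]
        )
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # Grow column by column; the first column that fails to raise the
            # rank is the collinear one.
            r_prev = 0
            for j in range(design.shape[1]):
                r = np.linalg.matrix_rank(design[:, : j + 1])
                if r == r_prev:
                    raise CollinearityError(
                        f"design matrix rank deficient: column {names[j]!r} is "
                        "collinear with the preceding columns"
                    )
                r_prev = r
        sv = np.linalg.svd(design, compute_uv=False)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "condition_number", float(sv[0] / sv[-1]))

    @property
    def n_interference(self) -> int:
        return self.interference.n_components

    @property
    def b_index(self) -> int:
        return self.poly_order + 1


@dataclass(frozen=True)
class EMSCFit:
    """Per-spectrum least-squares coefficients."""

    a: float
    c: np.ndarray  # polynomial coefficients c_1..c_p
    b: float
    d: np.ndarray  # interference coefficients d_1..d_k
    rmse: float


def build_emsc_model(
    ds: SpectralDataset | np.ndarray,
    interference: InterferenceBasis,
    poly_order: int = DEFAULT_POLY_ORDER,
    axis: np.ndarray | None = None,
    b_min: float = DEFAULT_B_MIN,
) -> EMSCModel:
    """Assemble an EMSC model with the dataset mean as the reference."""
    if isinstance(ds, SpectralDataset):
        matrix, axis = ds.matrix, ds.axis
    else:
        matrix = np.atleast_2d(np.asarray(ds, dtype=float))
        if axis is None:
            raise ParameterError("axis is required when passing a bare matrix")
    reference = matrix.mean(axis=0)
    model = EMSCModel(reference, poly_order, interference, np.asarray(axis, dtype=float), b_min)
    logger.info("EMSC design matrix condition number: %.6g", model.condition_number)
    return model


def _solve(model: EMSCModel, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of one or more spectra onto the design; returns (coeffs, rmse)."""
    coeffs, *_ = np.linalg.lstsq(model.design, rows.T, rcond=None)
    resid = rows.T - model.design @ coeffs
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    return coeffs.T, rmse


def fit_emsc(spectrum: np.ndarray, model: EMSCModel) -> EMSCFit:
    """Ordinary least squares of one spectrum onto the EMSC design matrix."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size != model.axis.size:
        raise ParameterError("spectrum not aligned to model axis")
    coeffs, rmse = _solve(model, spectrum[None, :])
    coeffs = coeffs[0]
    p = model.poly_order
    fit = EMSCFit(
        a=float(coeffs[0]),
        c=coeffs[1 : p + 1].copy(),
        b=float(coeffs[model.b_index]),
        d=coeffs[model.b_index + 1 :].copy(),
        rmse=float(rmse[0]),
    )
    if abs(fit.b) <= model.b_min:
        raise DegenerateFitError(
            f"reference coefficient |b|={abs(fit.b):.3g} <= b_min={model.b_min}; "
            "spectrum unrelated to the reference"
        )
    return fit


def correct_spectrum(spectrum: np.ndarray, fit: EMSCFit, model: EMSCModel) -> np.ndarray:
    """Neutralize baseline and interference, divide out the scatter factor."""
    if abs(fit.b) <= model.b_min:
        raise DegenerateFitError(f"degenerate fit: |b|={abs(fit.b):.3g}")
    spectrum = np.asarray(spectrum, dtype=float)
    t = _scaled_axis(model.axis)
    poly = np.vander(t, model.poly_order + 1, increasing=True)[:, 1:]
    background = fit.a + poly @ fit.c + model.interference.components.T @ fit.d
    return (spectrum - background) / fit.b


def correct_dataset(
    ds: SpectralDataset, model: EMSCModel
) -> tuple[SpectralDataset, pd.DataFrame, list[str]]:
    """Fit + correct every spectrum; degenerate fits are quarantined, not fatal.

    Returns the corrected dataset (quarantined spectra pass through
    uncorrected), the per-spectrum coefficient table and the quarantine list
    of spectrum ids.
    """
    coeffs, rmse = _solve(model, ds.matrix)
    p = model.poly_order
    b = coeffs[:, model.b_index]
    quarantine: list[str] = []
    corrected = ds.matrix.copy()
    t = _scaled_axis(model.axis)
    poly = np.vander(t, p + 1, increasing=True)[:, 1:]
    background = (
        coeffs[:, [0]]
        + coeffs[:, 1 : p + 1] @ poly.T
        + coeffs[:, model.b_index + 1 :] @ model.interference.components
    )
    ok = np.abs(b) > model.b_min
    corrected[ok] = (ds.matrix[ok] - background[ok]) / b[ok, None]
    for sid in ds.meta.loc[~ok, "spectrum_id"]:
        quarantine.append(str(sid))
    if quarantine:
        logger.warning("EMSC quarantined %d degenerate fits: %s", len(quarantine), quarantine[:5])
    table = pd.DataFrame(
        {
            "spectrum_id": ds.meta["spectrum_id"].to_numpy(),
            "a": coeffs[:, 0],
            **{f"c{i}": coeffs[:, i] for i in range(1, p + 1)},
            "b": b,
            **{
                f"d{j + 1}": coeffs[:, model.b_index + 1 + j]
                for j in range(model.n_interference)
            },
            "rmse": rmse,
        }
    )
    return ds.with_matrix(corrected), table, quarantine


class EMSCCorrector(BaseEstimator, TransformerMixin):
    """PCA-seeded EMSC as a scikit-learn transformer.

    Parameters
    ----------
    poly_order : int, default 4
        Degree of the baseline polynomial in the design matrix.
    n_components : int or None
        Fixed number of PCA interference components; 5 reproduces the
        published configuration.  ``None`` selects by variance threshold.
    variance_threshold : float, default 0.96
        Smallest k with cumulative explained variance >= threshold is used
        when ``n_components`` is None (capped at ``max_components``).
    b_min : float, default 1e-6
        Guard on the multiplicative reference coefficient before division.

    Attributes
    ----------
    reference_ : ndarray
        Training-set mean spectrum.
    interference_ : InterferenceBasis
        Orthonormal PCA loadings used as interference columns.
    model_ : EMSCModel
        Assembled design matrix.
    coefficients_ : DataFrame
        Per-spectrum (a, c_i, b, d_j, rmse) table from the last transform.
    quarantine_ : list of str
        Spectrum ids whose fit was degenerate in the last transform.
    """

    def __init__(
        self,
        poly_order: int = DEFAULT_POLY_ORDER,
        n_components: int | None = None,
        variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
        max_components: int = DEFAULT_MAX_COMPONENTS,
        b_min: float = DEFAULT_B_MIN,
    ) -> None:
        self.poly_order = poly_order
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.max_components = max_components
        self.b_min = b_min

    def fit(self, X, y=None, axis: np.ndarray | None = None):
        X = check_array(X)
        self.axis_ = (
            np.asarray(axis, dtype=float)
            if axis is not None
            else np.arange(X.shape[1], dtype=float) + 1.0
        )
        self.interference_ = extract_interference_components(
            X, self.n_components, self.variance_threshold, self.max_components
        )
        self.model_ = build_emsc_model(
            X, self.interference_, self.poly_order, axis=self.axis_, b_min=self.b_min
        )
        self.reference_ = self.model_.reference
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, spectrum_ids=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        ids = (
            list(spectrum_ids)
            if spectrum_ids is not None
            else [f"row_{i}" for i in range(X.shape[0])]
        )
        meta = pd.DataFrame(
            {
                "spectrum_id": ids,
                "sample_id": "NW1_NA",
                "tissue_class": "NA",
                "weight_class": "NW",
                "roi_id": "r0",
                "x_um": np.arange(X.shape[0], dtype=float),
                "y_um": 0.0,
            }
        )
        ds = SpectralDataset(self.axis_, X, meta)
        corrected, table, quarantine = correct_dataset(ds, self.model_)
        self.coefficients_ = table
        self.quarantine_ = quarantine
        return corrected.matrix


def correct_dataset_with_pca(
    ds: SpectralDataset,
    poly_order: int = DEFAULT_POLY_ORDER,
    n_components: int | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    b_min: float = DEFAULT_B_MIN,
) -> tuple[SpectralDataset, pd.DataFrame, EMSCModel]:
    """One-call convenience: PCA on ``ds``, model from ``ds``, correct ``ds``."""
    basis = extract_interference_components(ds, n_components, variance_threshold, max_components)
    model = build_emsc_model(ds, basis, poly_order, b_min=b_min)
    corrected, table, quarantine = correct_dataset(ds, model)
    if quarantine:
        table.attrs["quarantine"] = quarantine
    return corrected, table, model
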