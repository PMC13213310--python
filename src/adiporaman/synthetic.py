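"""Synthetic adipocyte Raman cohorts with planted, recorded ground truth.

The generator emulates the statistical structure the pipeline assumes:

* Lorentzian (optionally Gaussian) lipid bands at the canonical adipocyte
  positions — 1267, 1301, 1440 (CH2 scissoring), 1655 (C=C stretch), 1745
  (C=O ester stretch) cm^-1 in the fingerprint window; 2840/2880 (CH2
  symmetric/asymmetric stretch), 2930 and 3010 (=C-H stretch) cm^-1 in the
  high-wavenumber window;
* carotenoid bands at 1004, 1155 and 1520 cm^-1 whose joint amplitude is a
  per-spectrum lognormal draw, emulating the temperature-sensitive resonance
  Raman intensity that the EMSC stage must neutralize;
* class-dependent multiplicative band effects (tissue class NA/CAA crossed
  with weight class NW/OW), with patient-level random effects plus
  per-spectrum jitter, so per-sample clustering tendencies are reproduced
  in kind;
* polynomial baseline drift, a global lognormal multiplicative scatter
  factor, and additive Gaussian noise.

Every random quantity drawn for a spectrum is recorded in a ground-truth
table, so downstream tests can use the planted values as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import MapGeometry, SpectralDataset, build_map_grid
from .exceptions import ParameterError


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: position, width (FWHM), peak height, line shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"
    assignment: str = ""
    is_carotenoid: bool = False

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.amplitude < 0:
            raise ParameterError("band needs fwhm > 0 and amplitude >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ParameterError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Band line shape evaluated on the axis; peak height = amplitude."""
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "lorentzian":
            half = self.fwhm / 2.0
            return self.amplitude / (1.0 + (x / half) ** 2)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)


#: Default band library.  Carotenoid FWHMs are on the narrow side of the
#: 10-20 cm^-1 condensed-phase range; C-H stretch bands are broader.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1004.0, 10.0, 0.30, "lorentzian", "C-C stretch / CH3 rock (carotenoid)", True),
    BandSpec(1155.0, 12.0, 0.50, "lorentzian", "C-C stretch (carotenoid)", True),
    BandSpec(1267.0, 16.0, 0.25, "lorentzian", "=C-H in-plane bend (unsaturated lipid)"),
    BandSpec(1301.0, 16.0, 0.50, "lorentzian", "CH2 twist (lipid)"),
    BandSpec(1440.0, 18.0, 1.00, "lorentzian", "CH2 scissoring (lipid)"),
    BandSpec(1520.0, 14.0, 1.00, "lorentzian", "C=C stretch (carotenoid)", True),
    BandSpec(1655.0, 18.0, 0.60, "lorentzian", "C=C stretch (unsaturated lipid)"),
    BandSpec(1745.0, 16.0, 0.30, "lorentzian", "C=O ester stretch (triglyceride)"),
    BandSpec(2840.0, 20.0, 1.60, "lorentzian", "CH2 symmetric stretch (lipid)"),
    BandSpec(2880.0, 20.0, 1.40, "lorentzian", "CH2 asymmetric stretch (lipid)"),
    BandSpec(2930.0, 20.0, 0.70, "lorentzian", "CH3 symmetric stretch"),
    BandSpec(3010.0, 18.0, 0.40, "lorentzian", "=C-H stretch (unsaturated lipid)"),
)


@dataclass(frozen=True)
class ClassProfile:
    """Multiplicative band effects of one tissue x weight stratum.

    ``band_multipliers`` maps band center (cm^-1) to the mean multiplier;
    unlisted bands keep multiplier 1.  ``effect_sd`` is the lognormal sigma
    of the per-spectrum jitter around each multiplier.
    """

    tissue_class: str
    weight_class: str
    band_multipliers: dict[float, float] = field(default_factory=dict)
    effect_sd: float = 0.03

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.band_multipliers.values()):
            raise ParameterError("band multipliers must be positive")

    def multiplier(self, center: float) -> float:
        return self.band_multipliers.get(center, 1.0)


def default_class_profiles() -> dict[tuple[str, str], ClassProfile]:
    """NA/NW is the identity reference; CAA raises lipid unsaturation markers
    (1655, 3010, 1267) and lowers triglyceride-storage markers (1745, 2880);
    obesity damps the unsaturation shift.  Effects are deliberately subtle
    (a few percent to ~15%): the class contrast must stay far below the
    carotenoid-interference variance, which is the regime the correction
    stage is designed for."""
    return {
        ("NA", "NW"): ClassProfile("NA", "NW"),
        ("NA", "OW"): ClassProfile("NA", "OW", {1655.0: 0.96, 3010.0: 0.96}),
        ("CAA", "NW"): ClassProfile(
            "CAA", "NW",
            {1655.0: 1.12, 3010.0: 1.15, 1267.0: 1.08, 1745.0: 0.92, 2880.0: 0.95},
        ),
        ("CAA", "OW"): ClassProfile(
            "CAA", "OW",
            {1655.0: 1.08, 3010.0: 1.10, 1267.0: 1.05, 1745.0: 0.94, 2880.0: 0.96},
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation settings.

    Defaults reproduce the acquisition design being emulated: 5 normal-weight
    and 5 obese-weight patients, NA and CAA tissue from each, one
    30 um x 30 um map per tissue at 1 um step (961 spectra per map), and the
    two analysis windows 900-1800 / 2700-3100 cm^-1 sampled at 1 cm^-1.
    """

    regions: tuple[tuple[float, float], ...] = ((900.0, 1800.0), (2700.0, 3100.0))
    axis_step: float = 1.0
    n_patients_per_weight: int = 5
    maps_per_patient: int = 1
    grid: MapGeometry = field(default_factory=MapGeometry)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    class_profiles: dict[tuple[str, str], ClassProfile] = field(
        default_factory=default_class_profiles
    )
    carotenoid_amp_mu: float = 0.0
    carotenoid_amp_sigma: float = 0.7
    carotenoid_shift_sd: float = 1.5
    carotenoid_width_sigma: float = 0.08
    carotenoid_ratio_sigma: float = 0.2
    baseline_order: int = 3
    baseline_scale: float = 0.5
    scatter_sigma: float = 0.15
    noise_sd: float = 0.01
    patient_effect_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for value in (
            self.carotenoid_amp_sigma, self.carotenoid_shift_sd,
            self.carotenoid_width_sigma, self.carotenoid_ratio_sigma,
            self.baseline_scale, self.scatter_sigma,
            self.noise_sd, self.patient_effect_sd,
        ):
            if value < 0:
                raise ParameterError("all generator scales must be >= 0")
        if self.axis_step <= 0:
            raise ParameterError("axis_step must be > 0")

    def build_axis(self) -> np.ndarray:
        parts = [
            np.arange(lo, hi + self.axis_step / 2, self.axis_step) for lo, hi in self.regions
        ]
        return np.concatenate(parts)


def generate_spectrum(
    bands: tuple[BandSpec, ...],
    class_profile: ClassProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    axis: np.ndarray | None = None,
    patient_multipliers: dict[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """One synthetic spectrum plus the ground-truth record of its draws.

    intensity = scatter * [ sum(lipid bands x multipliers)
                            + carotenoid_amp * sum(carotenoid bands)
                            + baseline polynomial ] + noise

    The carotenoid bands additionally share a per-spectrum position shift and
    width factor, and each carries its own relative-amplitude jitter: the
    resonance enhancement that scales their intensity is temperature
    dependent, the same temperature variation shifts and broadens the bands,
    and the mix of carotenoid species varies between cells, so the carotenoid
    contribution forms a multi-dimensional manifold rather than a single
    linear direction — the structure the PCA interference basis has to
    capture.
    """
    axis = config.build_axis() if axis is None else np.asarray(axis, dtype=float)
    patient_multipliers = patient_multipliers or {}
    t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0

    carotenoid_shift = (
        rng.normal(0.0, config.carotenoid_shift_sd) if config.carotenoid_shift_sd > 0 else 0.0
    )
    carotenoid_width = (
        rng.lognormal(0.0, config.carotenoid_width_sigma)
        if config.carotenoid_width_sigma > 0
        else 1.0
    )

    signal = np.zeros_like(axis)
    carotenoid_profile = np.zeros_like(axis)
    truth: dict = {}
    for band in bands:
        if band.is_carotenoid:
            ratio = (
                rng.lognormal(0.0, config.carotenoid_ratio_sigma)
                if config.carotenoid_ratio_sigma > 0
                else 1.0
            )
            jittered = replace(
                band,
                center=band.center + carotenoid_shift,
                fwhm=band.fwhm * carotenoid_width,
                amplitude=band.amplitude * ratio,
            )
            carotenoid_profile += jittered.profile(axis)
            continue
        mult = class_profile.multiplier(band.center) * patient_multipliers.get(band.center, 1.0)
        if class_profile.effect_sd > 0:
            mult *= rng.lognormal(0.0, class_profile.effect_sd)
        signal += mult * band.profile(axis)
        truth[f"mult_{band.center:.0f}"] = mult

    carotenoid_amp = (
        rng.lognormal(config.carotenoid_amp_mu, config.carotenoid_amp_sigma)
        if config.carotenoid_amp_sigma > 0 or config.carotenoid_amp_mu != 0
        else 1.0
    )
    baseline_coeffs = np.concatenate(
        [rng.uniform(0.5, 1.5, size=1), rng.uniform(-0.5, 0.5, size=config.baseline_order)]
    ) * config.baseline_scale
    baseline = np.polynomial.polynomial.polyval(t, baseline_coeffs)
    scatter = rng.lognormal(0.0, config.scatter_sigma) if config.scatter_sigma > 0 else 1.0
    noise = rng.normal(0.0, config.noise_sd, size=axis.size) if config.noise_sd > 0 else 0.0

    intensity = scatter * (signal + carotenoid_amp * carotenoid_profile + baseline) + noise
    truth.update(carotenoid_amp=carotenoid_amp, carotenoid_shift=carotenoid_shift,
                 carotenoid_width=carotenoid_width, scatter=scatter,
                 baseline_c0=baseline_coeffs[0])
    return intensity, truth


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[SpectralDataset, pd.DataFrame]:
    """Full synthetic cohort with metadata and a planted ground-truth table.

    Patients NW1..NWn and OW1..OWn each contribute one NA and one CAA sample
    (sample ids like ``NW5_CAA``), with ``maps_per_patient`` raster maps per
    sample.  The same seed always reproduces the cohort bit-exactly.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.build_axis()
    grid = build_map_grid(cfg.grid)

    rows, meta_rows, truth_rows = [], [], []
    non_carotenoid = [b for b in cfg.bands if not b.is_carotenoid]
    for weight in ("NW", "OW"):
        for p in range(1, cfg.n_patients_per_weight + 1):
            # One multiplier draw per patient and band: patient-level random
            # effect shared by all of that patient's spectra.
            patient_mults = {
                b.center: float(rng.lognormal(0.0, cfg.patient_effect_sd))
                for b in non_carotenoid
            } if cfg.patient_effect_sd > 0 else {}
            for tissue in ("NA", "CAA"):
                sample_id = f"{weight}{p}_{tissue}"
                profile = cfg.class_profiles[(tissue, weight)]
                for roi in range(cfg.maps_per_patient):
                    roi_id = f"roi{roi}"
                    for x_um, y_um in grid:
                        spectrum_id = f"{sample_id}_{roi_id}_x{x_um:g}_y{y_um:g}"
                        intensity, truth = generate_spectrum(
                            cfg.bands, profile, cfg, rng, axis, patient_mults
                        )
                        rows.append(intensity)
                        meta_rows.append(
                            dict(
                                spectrum_id=spectrum_id, sample_id=sample_id,
                                tissue_class=tissue, weight_class=weight,
                                roi_id=roi_id, x_um=float(x_um), y_um=float(y_um),
                            )
                        )
                        truth_rows.append(dict(spectrum_id=spectrum_id, **truth))

    ds = SpectralDataset(axis, np.vstack(rows), pd.DataFrame(meta_rows))
    return ds, pd.DataFrame(truth_rows)


def small_cohort_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Reduced cohort for fast tests: coarser axis, 4x4 um maps (25 spectra
    each), 2 patients per weight class.  Statistical structure is unchanged."""
    defaults = dict(
        axis_step=3.0,
        n_patients_per_weight=2,
        grid=MapGeometry(4.0, 4.0, 1.0),
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
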