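"""Core data model for hyperspectral Raman maps.

A :class:`SpectralDataset` couples a strictly increasing wavenumber axis
(cm^-1) with an ``n_spectra x n_channels`` intensity matrix and one metadata
row per spectrum (sample id, tissue class NA/CAA, weight class NW/OW, ROI id,
map coordinates in micrometres).  Every pipeline stage consumes and returns
this object.

Acquisition maps are square regions of interest rastered with a motorized
stage; :func:`build_map_grid` reproduces the border-inclusive pixel lattice
(a 30 um x 30 um ROI at 1 um step yields 31 x 31 = 961 positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyRegionError,
    ExtrapolationError,
    InvalidGeometryError,
    SpectralFormatError,
)

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("NA", "CAA")
WEIGHT_CLASSES = ("NW", "OW")

#: Metadata columns, in file order.
META_COLUMNS = (
    "spectrum_id",
    "sample_id",
    "tissue_class",
    "weight_class",
    "roi_id",
    "x_um",
    "y_um",
)

WAVENUMBER_COLUMN = "wavenumber_cm-1"


def _validate_axis(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise SpectralFormatError("wavenumber axis must be 1-D with length >= 2")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise SpectralFormatError("wavenumber axis must be finite and positive")
    if not np.all(np.diff(values) > 0):
        raise SpectralFormatError("wavenumber axis must be strictly increasing")
    return values


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region bounds must satisfy lo < hi, got ({self.lo}, {self.hi})")


#: Analysis regions: fingerprint and high-wavenumber windows, skipping the
#: biologically silent ~1800-2700 cm^-1 interval.
FINGERPRINT = SpectralRegion("fingerprint", 900.0, 1800.0)
HIGH_WAVENUMBER = SpectralRegion("high_wavenumber", 2700.0, 3100.0)
REGIONS: Mapping[str, SpectralRegion] = {
    "fingerprint": FINGERPRINT,
    "high_wavenumber": HIGH_WAVENUMBER,
}


@dataclass(frozen=True)
class MapGeometry:
    """Raster-map extent and step, micrometres."""

    width_um: float = 30.0
    height_um: float = 30.0
    step_um: float = 1.0

    def __post_init__(self) -> None:
        if self.step_um <= 0:
            raise InvalidGeometryError(f"step_um must be > 0, got {self.step_um}")
        if self.width_um < 0 or self.height_um < 0:
            raise InvalidGeometryError("map extents must be non-negative")
        for extent in (self.width_um, self.height_um):
            ratio = extent / self.step_um
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidGeometryError(
                    f"extent {extent} um is not an integer multiple of step {self.step_um} um"
                )

    @property
    def n_x(self) -> int:
        return int(round(self.width_um / self.step_um)) + 1

    @property
    def n_y(self) -> int:
        return int(round(self.height_um / self.step_um)) + 1


def build_map_grid(geom: MapGeometry) -> np.ndarray:
    """Return the (n_x * n_y, 2) array of (x_um, y_um) raster positions.

    Borders are inclusive and the order is row-major (y outer, x inner), so a
    30 um square at 1 um step gives 961 positions.
    """
    xs = np.arange(geom.n_x) * geom.step_um
    ys = np.arange(geom.n_y) * geom.step_um
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _validate_meta(meta: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectralFormatError(f"metadata missing columns: {missing}")
    if len(meta) != n_rows:
        raise SpectralFormatError(
            f"metadata has {len(meta)} rows but matrix has {n_rows} spectra"
        )
    bad_t = set(meta["tissue_class"]) - set(TISSUE_CLASSES)
    if bad_t:
        raise SpectralFormatError(f"unknown tissue_class values: {sorted(bad_t)}")
    bad_w = set(meta["weight_class"]) - set(WEIGHT_CLASSES)
    if bad_w:
        raise SpectralFormatError(f"unknown weight_class values: {sorted(bad_w)}")
    key = meta[["sample_id", "roi_id", "x_um", "y_um"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise SpectralFormatError(f"duplicate (sample_id, roi_id, x_um, y_um) tuple: {dup}")
    return meta.reset_index(drop=True)


@dataclass
class SpectralDataset:
    """Wavenumber axis + intensity matrix + per-spectrum metadata."""

    axis: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.axis.size:
            raise SpectralFormatError(
                f"matrix has {self.matrix.shape[1]} channels but axis has {self.axis.size}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise SpectralFormatError("intensity matrix contains non-finite values")
        self.meta = _validate_meta(self.meta, self.matrix.shape[0])

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectralDataset(
            self.axis.copy(), self.matrix[mask], self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
        )

    def with_matrix(self, matrix: np.ndarray) -> "SpectralDataset":
        """Same axis and metadata, new intensities."""
        return SpectralDataset(self.axis.copy(), matrix, self.meta.copy())


def parse_sample_id(sample_id: str) -> tuple[str, str]:
    """Split ``<weight_class><index>_<tissue_class>`` (e.g. ``NW5_CAA``).

    Returns (weight_class, tissue_class).
    """
    try:
        head, tissue = sample_id.split("_")
    except ValueError as exc:
        raise SpectralFormatError(f"sample_id {sample_id!r} not of form NW5_CAA") from exc
    weight = head.rstrip("0123456789")
    if weight not in WEIGHT_CLASSES or tissue not in TISSUE_CLASSES:
        raise SpectralFormatError(f"sample_id {sample_id!r} has unknown class labels")
    return weight, tissue


def cut_region(ds: SpectralDataset, region: SpectralRegion) -> SpectralDataset:
    """Restrict a dataset to channels with lo <= wavenumber <= hi."""
    mask = (ds.axis >= region.lo) & (ds.axis <= region.hi)
    if not mask.any():
        raise EmptyRegionError(
            f"region {region.name} [{region.lo}, {region.hi}] does not intersect "
            f"axis [{ds.axis[0]}, {ds.axis[-1]}]"
        )
    return SpectralDataset(ds.axis[mask], ds.matrix[:, mask], ds.meta.copy())


def resample_to_common_axis(
    datasets: Sequence[SpectralDataset], target: np.ndarray
) -> SpectralDataset:
    """Linearly interpolate every spectrum onto ``target`` and concatenate rows.

    Each source axis must span the target axis; extrapolation is refused.
    """
    target = _validate_axis(np.asarray(target, dtype=float))
    rows = []
    metas = []
    for i, ds in enumerate(datasets):
        if target[0] < ds.axis[0] - 1e-12 or target[-1] > ds.axis[-1] + 1e-12:
            raise ExtrapolationError(
                f"dataset {i}: target [{target[0]}, {target[-1]}] extends beyond "
                f"source axis [{ds.axis[0]}, {ds.axis[-1]}]"
            )
        if ds.axis.size == target.size and np.array_equal(ds.axis, target):
            rows.append(ds.matrix)
        else:
            rows.append(
                np.vstack([np.interp(target, ds.axis, row) for row in ds.matrix])
            )
        metas.append(ds.meta)
    return SpectralDataset(
        target, np.vstack(rows), pd.concat(metas, ignore_index=True)
    )


def mean_spectrum(ds: SpectralDataset, group_by: str | None = None) -> dict[str, np.ndarray]:
    """Arithmetic mean spectrum per group of a metadata field.

    With ``group_by=None`` returns ``{"all": mean over every spectrum}``.
    """
    if ds.n_spectra == 0:
        raise SpectralFormatError("cannot average an empty dataset")
    if group_by is None:
        return {"all": ds.matrix.mean(axis=0)}
    if group_by not in ds.meta.columns:
        raise SpectralFormatError(f"unknown metadata field {group_by!r}")
    out: dict[str, np.ndarray] = {}
    for label, idx in ds.meta.groupby(group_by, sort=True).groups.items():
        out[str(label)] = ds.matrix[np.asarray(idx)].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Text I/O.  Spectral matrix: delimited text, first column the wavenumber
# axis, one column per spectrum, header row carrying spectrum ids.
# Metadata: CSV keyed by spectrum_id.
# ---------------------------------------------------------------------------

def _sniff_delimiter(header: str) -> str:
    for delim in ("\t", ",", ";"):
        if delim in header:
            return delim
    raise SpectralFormatError("could not detect delimiter (expected tab, comma or semicolon)")


def read_dataset(path: str | Path, meta_path: str | Path) -> SpectralDataset:
    """Read a spectral matrix file plus its companion metadata CSV."""
    path, meta_path = Path(path), Path(meta_path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    frame = pd.read_csv(path, sep=delim)
    if frame.columns[0] != WAVENUMBER_COLUMN:
        raise SpectralFormatError(
            f"first column must be {WAVENUMBER_COLUMN!r}, got {frame.columns[0]!r}"
        )
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()][0]
        raise SpectralFormatError(f"ragged or missing values in column {bad!r}")
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    matrix = frame.iloc[:, 1:].to_numpy(dtype=float).T
    spectrum_ids = list(frame.columns[1:])
    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        logger.info("axis in %s is descending; reversing to ascending order", path)
        axis = axis[::-1]
        matrix = matrix[:, ::-1]
    diffs = np.diff(axis)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise SpectralFormatError(f"non-monotone wavenumber axis at data row {row} of {path}")

    # keep_default_na: the tissue class "NA" is a real label, not a missing value
    meta = pd.read_csv(meta_path, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectralFormatError(f"metadata {meta_path} missing columns: {missing}")
    meta = meta.set_index("spectrum_id", drop=False)
    absent = [sid for sid in spectrum_ids if sid not in meta.index]
    if absent:
        raise SpectralFormatError(f"metadata row missing for spectrum column {absent[0]!r}")
    meta = meta.loc[spectrum_ids].reset_index(drop=True)
    return SpectralDataset(axis, matrix, meta)


def write_dataset(ds: SpectralDataset, path: str | Path, meta_path: str | Path) -> None:
    """Write matrix + metadata with 9 significant digits, tab-delimited."""
    path, meta_path = Path(path), Path(meta_path)
    ids = ds.meta["spectrum_id"].astype(str).tolist()
    frame = pd.DataFrame(ds.matrix.T, columns=ids)
    frame.insert(0, WAVENUMBER_COLUMN, ds.axis)
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
    ds.meta.loc[:, list(META_COLUMNS)].to_csv(meta_path, index=False)
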