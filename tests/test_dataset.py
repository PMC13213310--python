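"""Data model: map grids, region cutting, resampling, averaging, text I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adiporaman as ar
from adiporaman.dataset import parse_sample_id
from adiporaman.exceptions import (
    EmptyRegionError,
    ExtrapolationError,
    InvalidGeometryError,
    SpectralFormatError,
)
from helpers import make_dataset


class TestMapGrid:
    @pytest.mark.parametrize(
        "width,height,step,expected",
        [(30, 30, 1, 961), (0, 0, 1, 1), (2, 3, 1, 12)],
    )
    def test_position_counts(self, width, height, step, expected):
        grid = ar.build_map_grid(ar.MapGeometry(width, height, step))
        assert grid.shape == (expected, 2)
        # border-inclusive lattice: no duplicates, extremes present
        assert len({tuple(p) for p in grid}) == expected
        assert grid[:, 0].max() == width and grid[:, 1].max() == height

    def test_row_major_order(self):
        grid = ar.build_map_grid(ar.MapGeometry(2, 1, 1))
        assert grid.tolist() == [[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1]]

    @given(
        nx=st.integers(0, 40), ny=st.integers(0, 40),
        step=st.sampled_from([0.5, 1.0, 2.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_formula(self, nx, ny, step):
        geom = ar.MapGeometry(nx * step, ny * step, step)
        assert len(ar.build_map_grid(geom)) == (nx + 1) * (ny + 1)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            ar.MapGeometry(30, 30, 0)
        with pytest.raises(InvalidGeometryError):
            ar.MapGeometry(30, 30, -1)
        with pytest.raises(InvalidGeometryError):
            ar.MapGeometry(5, 5, 2)  # extent not a multiple of step


class TestCutRegion:
    def test_keeps_only_channels_inside_bounds(self):
        axis = np.arange(800.0, 1801.0, 10.0)
        ds = make_dataset(axis, np.ones((3, axis.size)))
        cut = ar.cut_region(ds, ar.FINGERPRINT)
        assert cut.axis[0] == 900.0 and cut.axis[-1] == 1800.0
        assert cut.n_spectra == 3
        pd.testing.assert_frame_equal(cut.meta, ds.meta)

    def test_full_axis_region_is_identity(self):
        axis = np.arange(900.0, 1801.0, 10.0)
        ds = make_dataset(axis, np.random.default_rng(0).normal(size=(2, axis.size)))
        cut = ar.cut_region(ds, ar.SpectralRegion("fingerprint", 900, 1800))
        np.testing.assert_array_equal(cut.matrix, ds.matrix)
        np.testing.assert_array_equal(cut.axis, ds.axis)

    def test_disjoint_region_raises(self):
        axis = np.arange(800.0, 1801.0, 10.0)
        ds = make_dataset(axis, np.ones((1, axis.size)))
        with pytest.raises(EmptyRegionError):
            ar.cut_region(ds, ar.HIGH_WAVENUMBER)

    def test_idempotent(self):
        axis = np.arange(800.0, 1801.0, 7.0)
        ds = make_dataset(axis, np.random.default_rng(1).normal(size=(2, axis.size)))
        once = ar.cut_region(ds, ar.FINGERPRINT)
        twice = ar.cut_region(once, ar.FINGERPRINT)
        np.testing.assert_array_equal(once.matrix, twice.matrix)
        np.testing.assert_array_equal(once.axis, twice.axis)


class TestResample:
    def test_identical_axes_bitwise_concatenation(self):
        axis = np.arange(900.0, 1001.0, 5.0)
        a = make_dataset(axis, np.random.default_rng(2).normal(size=(2, axis.size)), "NW1_NA")
        b = make_dataset(axis, np.random.default_rng(3).normal(size=(3, axis.size)), "OW1_CAA")
        merged = ar.resample_to_common_axis([a, b], axis)
        assert merged.n_spectra == 5
        np.testing.assert_array_equal(merged.matrix[:2], a.matrix)
        np.testing.assert_array_equal(merged.matrix[2:], b.matrix)

    def test_affine_spectra_exact(self):
        src = np.arange(900.0, 1101.0, 10.0)
        target = np.arange(905.0, 1091.0, 7.0)
        spectrum = 3.0 * src - 1000.0
        ds = make_dataset(src, spectrum)
        out = ar.resample_to_common_axis([ds], target)
        np.testing.assert_allclose(out.matrix[0], 3.0 * target - 1000.0, rtol=0, atol=1e-9)

    def test_matches_two_point_interpolation_oracle(self, rng):
        src = np.sort(rng.uniform(900, 1800, 80))
        src[0], src[-1] = 900.0, 1800.0
        spectrum = np.sin(src / 50.0) + 0.1 * rng.normal(size=src.size)
        target = np.sort(rng.uniform(901, 1799, 40))
        ds = make_dataset(src, spectrum)
        out = ar.resample_to_common_axis([ds], target)
        # independent piecewise-linear oracle: direct two-point formula
        expected = np.empty_like(target)
        for j, nu in enumerate(target):
            i = np.searchsorted(src, nu) - 1
            w = (nu - src[i]) / (src[i + 1] - src[i])
            expected[j] = (1 - w) * spectrum[i] + w * spectrum[i + 1]
        np.testing.assert_allclose(out.matrix[0], expected, rtol=0, atol=1e-12)

    def test_extrapolation_refused(self):
        src = np.arange(900.0, 1001.0, 5.0)
        ds = make_dataset(src, np.ones(src.size))
        with pytest.raises(ExtrapolationError):
            ar.resample_to_common_axis([ds], np.arange(850.0, 1001.0, 5.0))


class TestMeanSpectrum:
    def test_identical_spectra(self):
        axis = np.arange(900.0, 1001.0, 5.0)
        row = np.sin(axis / 30)
        ds = make_dataset(axis, np.tile(row, (4, 1)))
        np.testing.assert_allclose(ar.mean_spectrum(ds)["all"], row)

    def test_two_row_average(self):
        axis = np.arange(900.0, 921.0, 10.0)
        ds = make_dataset(axis, np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]))
        np.testing.assert_array_equal(ar.mean_spectrum(ds)["all"], [1.0, 1.0, 1.0])

    def test_matches_column_sum_oracle_per_group(self, rng):
        axis = np.arange(900.0, 1001.0, 5.0)
        m = rng.normal(size=(6, axis.size))
        meta = pd.DataFrame(
            {
                "spectrum_id": [f"s{i}" for i in range(6)],
                "sample_id": ["NW1_NA"] * 3 + ["NW1_CAA"] * 3,
                "tissue_class": ["NA"] * 3 + ["CAA"] * 3,
                "weight_class": "NW",
                "roi_id": "roi0",
                "x_um": np.arange(6, dtype=float),
                "y_um": 0.0,
            }
        )
        ds = ar.SpectralDataset(axis, m, meta)
        means = ar.mean_spectrum(ds, "tissue_class")
        np.testing.assert_allclose(means["NA"], m[:3].sum(axis=0) / 3, atol=1e-12)
        np.testing.assert_allclose(means["CAA"], m[3:].sum(axis=0) / 3, atol=1e-12)

    def test_unknown_field_raises(self):
        ds = make_dataset(np.arange(900.0, 921.0, 10.0), np.ones(3))
        with pytest.raises(SpectralFormatError):
            ar.mean_spectrum(ds, "no_such_field")


class TestIO:
    def test_round_trip(self, tmp_path, rng):
        axis = np.arange(900.0, 1101.0, 4.0)
        ds = make_dataset(axis, rng.normal(size=(5, axis.size)) * 100)
        ar.write_dataset(ds, tmp_path / "m.tsv", tmp_path / "meta.csv")
        back = ar.read_dataset(tmp_path / "m.tsv", tmp_path / "meta.csv")
        np.testing.assert_allclose(back.matrix, ds.matrix, rtol=1e-8)
        np.testing.assert_allclose(back.axis, ds.axis, rtol=1e-9)
        assert back.meta["spectrum_id"].tolist() == ds.meta["spectrum_id"].tolist()
        assert back.meta["sample_id"].tolist() == ds.meta["sample_id"].tolist()

    def test_missing_metadata_row_names_column(self, tmp_path):
        axis = np.arange(900.0, 921.0, 10.0)
        ds = make_dataset(axis, np.ones((2, 3)))
        ar.write_dataset(ds, tmp_path / "m.tsv", tmp_path / "meta.csv")
        meta = pd.read_csv(tmp_path / "meta.csv").iloc[:1]
        meta.to_csv(tmp_path / "meta.csv", index=False)
        with pytest.raises(SpectralFormatError, match="s1"):
            ar.read_dataset(tmp_path / "m.tsv", tmp_path / "meta.csv")

    def test_non_monotone_axis_rejected(self, tmp_path):
        axis = np.arange(900.0, 951.0, 10.0)
        ds = make_dataset(axis, np.ones((1, axis.size)))
        ar.write_dataset(ds, tmp_path / "m.tsv", tmp_path / "meta.csv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        lines[2], lines[3] = lines[3], lines[2]  # swap two axis rows
        (tmp_path / "m.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(SpectralFormatError, match="non-monotone"):
            ar.read_dataset(tmp_path / "m.tsv", tmp_path / "meta.csv")

    def test_descending_axis_reversed_on_read(self, tmp_path):
        axis = np.arange(900.0, 951.0, 10.0)
        ds = make_dataset(axis, np.arange(6.0))
        ar.write_dataset(ds, tmp_path / "m.tsv", tmp_path / "meta.csv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        flipped = [lines[0]] + lines[1:][::-1]
        (tmp_path / "m.tsv").write_text("\n".join(flipped) + "\n")
        back = ar.read_dataset(tmp_path / "m.tsv", tmp_path / "meta.csv")
        np.testing.assert_allclose(back.axis, axis)
        np.testing.assert_allclose(back.matrix[0], np.arange(6.0))


class TestInvariants:
    def test_duplicate_position_rejected(self):
        axis = np.arange(900.0, 921.0, 10.0)
        meta = pd.DataFrame(
            {
                "spectrum_id": ["a", "b"],
                "sample_id": "NW1_NA",
                "tissue_class": "NA",
                "weight_class": "NW",
                "roi_id": "roi0",
                "x_um": 0.0,
                "y_um": 0.0,
            }
        )
        with pytest.raises(SpectralFormatError, match="duplicate"):
            ar.SpectralDataset(axis, np.ones((2, 3)), meta)

    @pytest.mark.parametrize(
        "sid,expected",
        [("NW5_CAA", ("NW", "CAA")), ("OW1_NA", ("OW", "NA"))],
    )
    def test_parse_sample_id(self, sid, expected):
        assert parse_sample_id(sid) == expected

    def test_parse_sample_id_rejects_garbage(self):
        with pytest.raises(SpectralFormatError):
            parse_sample_id("XX3_CAA")
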