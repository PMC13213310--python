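"""EMSC: interference extraction, model assembly, fitting, correction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import adiporaman as ar
from adiporaman.emsc import _scaled_axis
from adiporaman.exceptions import CollinearityError, DegenerateFitError, RankError

AXIS = np.arange(900.0, 1800.0, 20.0)  # 45 channels


def random_model(rng, n_channels=45, k=2, poly_order=4):
    axis = np.linspace(900.0, 1800.0, n_channels)
    reference = 1.0 + np.exp(-0.5 * ((axis - 1440) / 30) ** 2)
    raw = rng.normal(size=(k, n_channels))
    # orthonormalize and keep components independent of the reference
    q, _ = np.linalg.qr(np.column_stack([reference, raw.T]))
    comps = q[:, 1 : k + 1].T
    basis = ar.InterferenceBasis(comps, np.linspace(0.6, 0.2, k) / k)
    return ar.EMSCModel(reference, poly_order, basis, axis)


class TestExtractInterference:
    def test_rank_one_dataset_single_component(self, rng):
        base = np.abs(rng.normal(size=60)) + 1.0
        scales = rng.uniform(0.5, 2.0, size=20)
        basis = ar.extract_interference_components(np.outer(scales, base), n_components=1)
        assert basis.n_components == 1
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_threshold_selects_planted_k(self, rng):
        # two orthogonal planted directions with variances 9 and 1:
        # cumulative explained ratio is 0.9 then 1.0, so 0.96 needs k = 2
        u = np.zeros(40); u[0] = 1.0
        v = np.zeros(40); v[1] = 1.0
        n = 4000
        scores = np.column_stack([
            rng.normal(0, 3.0, size=n), rng.normal(0, 1.0, size=n)
        ])
        X = scores @ np.vstack([u, v])
        basis = ar.extract_interference_components(X, variance_threshold=0.96)
        assert basis.n_components == 2

    def test_loadings_orthonormal_on_random_data(self, rng):
        X = rng.normal(size=(30, 25))
        basis = ar.extract_interference_components(X, n_components=5)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_k_exceeding_rank_raises(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=20))
        with pytest.raises(RankError):
            ar.extract_interference_components(X, n_components=5)


class TestBuildModel:
    def test_reference_is_dataset_mean(self, rng):
        X = rng.normal(size=(12, AXIS.size)) + 5.0
        basis = ar.extract_interference_components(X, n_components=2)
        model = ar.build_emsc_model(X, basis, axis=AXIS)
        np.testing.assert_allclose(model.reference, X.mean(axis=0), atol=1e-12)

    def test_identical_spectra_reference_equals_spectrum(self):
        row = 1.0 + np.exp(-0.5 * ((AXIS - 1155) / 10) ** 2)
        X = np.tile(row, (5, 1)) * np.array([[1.0], [2.0], [0.5], [1.5], [3.0]])
        basis = ar.InterferenceBasis(
            np.eye(AXIS.size)[:1], np.array([1.0])
        )
        model = ar.build_emsc_model(np.tile(row, (5, 1)), basis, axis=AXIS)
        np.testing.assert_allclose(model.reference, row)

    def test_interference_equal_to_reference_is_collinear(self):
        row = 1.0 + np.exp(-0.5 * ((AXIS - 1155) / 10) ** 2)
        comp = row / np.linalg.norm(row)
        basis = ar.InterferenceBasis(comp[None, :], np.array([1.0]))
        with pytest.raises(CollinearityError, match="interference_1"):
            ar.build_emsc_model(np.tile(row, (4, 1)), basis, axis=AXIS)

    def test_condition_number_matches_svd_oracle(self, rng):
        model = random_model(rng)
        sv = np.linalg.svd(model.design, compute_uv=False)
        assert model.condition_number == pytest.approx(sv[0] / sv[-1], rel=1e-6)


class TestFitAndCorrect:
    def test_offset_plus_scaled_reference(self, rng):
        model = random_model(rng)
        s = 1.0 + 2.0 * model.reference
        fit = ar.fit_emsc(s, model)
        assert fit.a == pytest.approx(1.0, abs=1e-10)
        assert fit.b == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.c, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.d, 0.0, atol=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(ar.correct_spectrum(s, fit, model), model.reference, atol=1e-10)

    def test_reference_plus_interference(self, rng):
        model = random_model(rng)
        s = model.reference + 0.5 * model.interference.components[0]
        fit = ar.fit_emsc(s, model)
        assert fit.b == pytest.approx(1.0, abs=1e-9)
        assert fit.d[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.rmse < 1e-10

    def test_span_member_with_drift_maps_to_reference(self, rng):
        model = random_model(rng)
        t = _scaled_axis(model.axis)
        s = model.reference + 0.8 * model.interference.components[0] + 0.3 * t**2 - 0.1 * t
        corrected = ar.correct_spectrum(s, ar.fit_emsc(s, model), model)
        np.testing.assert_allclose(corrected, model.reference, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        model = random_model(rng, n_channels=40, k=3)
        s = model.reference + rng.normal(0, 0.05, size=40)
        fit = ar.fit_emsc(s, model)
        X = model.design
        beta = np.linalg.solve(X.T @ X, X.T @ s)  # independent oracle
        assert fit.a == pytest.approx(beta[0], abs=1e-9)
        np.testing.assert_allclose(fit.c, beta[1:5], atol=1e-9)
        assert fit.b == pytest.approx(beta[5], abs=1e-9)
        np.testing.assert_allclose(fit.d, beta[6:], atol=1e-9)

    def test_degenerate_b_raises(self, rng):
        model = random_model(rng)
        # a spectrum orthogonal to the whole design span has b ~ 0
        q, _ = np.linalg.qr(np.column_stack([model.design, rng.normal(size=(45, 1))]))
        stray = q[:, -1]
        with pytest.raises(DegenerateFitError):
            ar.fit_emsc(stray, model)


class TestCorrectDataset:
    def test_span_exact_rows_all_map_to_reference(self, rng):
        model = random_model(rng)
        rows = np.vstack([
            0.5 + 1.5 * model.reference + 0.2 * model.interference.components[0],
            -1.0 + 0.7 * model.reference - 0.4 * model.interference.components[1],
        ])
        from helpers import make_dataset
        ds = make_dataset(model.axis, rows)
        corrected, table, quarantine = ar.correct_dataset(ds, model)
        assert quarantine == []
        for row in corrected.matrix:
            np.testing.assert_allclose(row, model.reference, atol=1e-8)
        np.testing.assert_allclose(table["b"], [1.5, 0.7], atol=1e-9)

    def test_quarantine_empty_on_generator_defaults(self, fingerprint_corrected):
        _, _, table, _, _ = fingerprint_corrected
        assert table.attrs.get("quarantine", []) == []
        assert (table["b"].abs() > 1e-6).all()

    def test_coefficient_table_round_trips_csv(self, fingerprint_corrected, tmp_path):
        _, _, table, _, _ = fingerprint_corrected
        path = tmp_path / "coeffs.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back["b"], table["b"], rtol=1e-12)

    def test_correction_operator_idempotent(self, fingerprint_corrected):
        # re-applying the fitted correction is a no-op: corrected spectra are
        # reference + residual, and the residual is orthogonal to the design
        _, corrected, _, model, _ = fingerprint_corrected
        twice, _, _ = ar.correct_dataset(corrected, model)
        scale = np.abs(corrected.matrix).max()
        assert np.max(np.abs(twice.matrix - corrected.matrix)) < 1e-6 * scale

    def test_variance_reduced_at_carotenoid_channels(self, fingerprint_corrected):
        cut, corrected, _, _, _ = fingerprint_corrected
        for center in (1004.0, 1155.0, 1520.0):
            ch = np.argmin(np.abs(cut.axis - center))
            assert corrected.matrix[:, ch].var() <= cut.matrix[:, ch].var()


class TestEstimatorAPI:
    def test_fit_transform_and_clone(self, rng):
        X = np.abs(rng.normal(size=(30, 50))) + np.linspace(1, 2, 50)
        est = ar.EMSCCorrector(n_components=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        out = est.fit(X).transform(X)
        assert out.shape == X.shape
        assert est.interference_.n_components == 3
        assert len(est.coefficients_) == 30

    def test_planted_amplitude_neutralized(self):
        # interference with a strictly positive planted amplitude: correction
        # must erase the correlation between amplitude and the peak channel
        cfg = ar.small_cohort_config(
            seed=5, carotenoid_shift_sd=0.0, carotenoid_width_sigma=0.0,
            carotenoid_ratio_sigma=0.0,
        )
        ds, truth = ar.generate_cohort(cfg)
        pre = ar.preprocess_dataset(ds)
        cut = ar.cut_region(pre, ar.FINGERPRINT)
        corrected, _, _ = ar.correct_dataset_with_pca(cut)
        alpha = truth["carotenoid_amp"].to_numpy()
        ch = np.argmin(np.abs(cut.axis - 1155.0))
        before = np.corrcoef(alpha, cut.matrix[:, ch])[0, 1]
        after = np.corrcoef(alpha, corrected.matrix[:, ch])[0, 1]
        assert before > 0.9
        assert abs(after) < 0.1
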