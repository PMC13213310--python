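"""Shared fixtures: reduced synthetic cohorts reused across test modules.

Session scope keeps the expensive generate -> preprocess -> EMSC chain to a
single execution per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

import adiporaman as ar


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (200 spectra, 3 cm^-1 axis) with its ground truth."""
    return ar.generate_cohort(ar.small_cohort_config(seed=0))


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    ds, _ = small_cohort
    return ar.preprocess_dataset(ds)


@pytest.fixture(scope="session")
def fingerprint_corrected(preprocessed, small_cohort):
    """EMSC-corrected fingerprint region plus fit table, model and truth."""
    _, truth = small_cohort
    cut = ar.cut_region(preprocessed, ar.FINGERPRINT)
    corrected, table, model = ar.correct_dataset_with_pca(cut)
    return cut, corrected, table, model, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
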