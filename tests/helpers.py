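"""Small shared test utilities."""

import numpy as np
import pandas as pd

import adiporaman as ar


def make_dataset(axis, matrix, sample_id="NW1_NA"):
    """Wrap a bare matrix in a SpectralDataset with minimal valid metadata."""
    n = np.atleast_2d(matrix).shape[0]
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "sample_id": sample_id,
            "tissue_class": sample_id.split("_")[1],
            "weight_class": sample_id[:2],
            "roi_id": "roi0",
            "x_um": np.arange(n, dtype=float),
            "y_um": 0.0,
        }
    )
    return ar.SpectralDataset(np.asarray(axis, float), np.atleast_2d(matrix), meta)
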