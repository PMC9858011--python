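import numpy as np
import pandas as pd
import pytest

from waspmon import spectra_io as io
from waspmon import synthetic_data as sd


def make_set(x, wavelengths=None, days=None, zones=None, specimens=None):
    """Small SpectraSet builder for hand fixtures."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if wavelengths is None:
        wavelengths = 1300.0 + 10.0 * np.arange(p)
    meta = pd.DataFrame(
        {
            "specimen_id": specimens if specimens is not None else [f"h{i}" for i in range(n)],
            "day": days if days is not None else [1] * n,
            "zone": zones if zones is not None else ["outer"] * n,
            "position": range(1, n + 1),
            "scan": [1] * n,
        }
    )
    return io.SpectraSet(io.SpectrumGrid(np.asarray(wavelengths, dtype=float)), x, meta)


@pytest.fixture(scope="session")
def default_data():
    """One seeded draw of the full 900-spectrum study design."""
    return sd.generate(sd.default_config(seed=1))


@pytest.fixture(scope="session")
def trimmed(default_data):
    return io.trim_range(default_data, 1300, 1600)
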