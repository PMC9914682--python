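import numpy as np
import pandas as pd
import pytest

from specerr.dataset import META_COLUMNS, SpectraDataset, WavelengthAxis


def make_dataset(X, wavelengths=None, sample="s1", session="1A", mode="A"):
    """SpectraDataset from a raw matrix with minimal single-group metadata."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if wavelengths is None:
        wavelengths = 1000.0 + 10.0 * np.arange(p)
    meta = pd.DataFrame(
        {
            "sample_id": [sample] * n,
            "session_id": [session] * n,
            "background_mode": [mode] * n,
            "replicate_index": np.arange(1, n + 1),
            "instrument_id": ["toy"] * n,
        },
        columns=list(META_COLUMNS),
    )
    return SpectraDataset(X, WavelengthAxis(np.asarray(wavelengths, float)), meta)


@pytest.fixture
def toy_pair():
    """Two replicates [1,3] and [3,5]: all hand-computed statistics known."""
    return make_dataset([[1.0, 3.0], [3.0, 5.0]])


@pytest.fixture(scope="session")
def emulated_design():
    """The full two-sample study layout on the 236-channel instrument."""
    from specerr.simulate import simulate_dataset

    return simulate_dataset(seed=2024)
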