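import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_blob_table(rng):
    """Two tight 11-variable groups separated by ~10 within-group sd."""
    n = 20
    a = rng.normal(0.0, 1.0, size=(n, 11))
    b = rng.normal(10.0, 1.0, size=(n, 11))
    X = np.vstack([a, b])
    truth = np.repeat([1, 2], n)
    table = pd.DataFrame(
        X,
        index=[f"S{i:03d}" for i in range(2 * n)],
        columns=[f"M{j:02d}" for j in range(11)],
    )
    return table, truth


@pytest.fixture
def raw_concentrations(rng):
    """Positive 'pg/mL'-like table: 24 samples x 5 markers, lognormal."""
    X = np.exp(rng.normal(np.log(50.0), 0.4, size=(24, 5)))
    return pd.DataFrame(
        X,
        index=[f"S{i:03d}" for i in range(24)],
        columns=["FGF", "VEGF", "MMP1", "MMP9", "IL8"],
    )
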