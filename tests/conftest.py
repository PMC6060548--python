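import numpy as np
import pandas as pd
import pytest

from peptivar.feature_table import FeatureTable


@pytest.fixture
def toy_table():
    """2 samples x 3 features raw table with one censored cell."""
    values = np.array([[2.0, 4.0, 6.0], [8.0, 8.0, 8.0]])
    below = np.array([[True, False, False], [False, False, False]])
    meta = pd.DataFrame({
        "sample_id": ["a", "b"],
        "subject_id": ["s1", "s2"],
    })
    return FeatureTable(values, [1000.0, 1500.0, 2000.0], meta, below_lod=below)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
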