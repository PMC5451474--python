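import numpy as np
import pandas as pd
import pytest

from mirnatime.containers import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 50-miRNA x 4-library count matrix with moderate depth."""
    ids = [f"mir-{i:03d}" for i in range(50)]
    labels = ["LR_35E", "LR_49E", "LT_35E", "LT_49E"]
    counts = rng.poisson(200.0, size=(50, 4))
    return CountMatrix(pd.DataFrame(counts, index=ids, columns=labels))
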