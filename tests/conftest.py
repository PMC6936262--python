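import numpy as np
import pandas as pd
import pytest

from plastiscope import FoldChangeMatrix


@pytest.fixture
def small_fc():
    """3 genes x 4 conditions with one missing cell."""
    values = pd.DataFrame(
        [[1.0, -1.0, 2.0, 0.0], [0.5, 0.5, np.nan, -0.5], [2.0, 2.0, -2.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return FoldChangeMatrix(values)


@pytest.fixture
def random_fc():
    """50 genes x 20 conditions, i.i.d. with scattered missing values."""
    rng = np.random.default_rng(42)
    values = rng.normal(0, 1.5, size=(50, 20))
    mask = rng.random(values.shape) < 0.1
    values[mask] = np.nan
    # guarantee at least one observation per row
    values[:, 0] = rng.normal(size=50)
    return FoldChangeMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(50)],
            columns=[f"c{j}" for j in range(20)],
        )
    )
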