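import numpy as np
import pandas as pd
import pytest

from schooldust import ConcentrationMatrix, default_background
from schooldust.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic survey (24 sites x 11 elements, seed 0)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def background():
    return default_background()


@pytest.fixture()
def small_matrix():
    """A tiny fixed concentration matrix for index arithmetic."""
    return ConcentrationMatrix(
        pd.DataFrame(
            {"As": [10.0, 20.0], "Fe": [1000.0, 2000.0]},
            index=["S1", "S2"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
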