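import numpy as np
import pytest

from apyield.synthdata import SyntheticConfig, generate_county_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 county-years (12 counties x 5 seasons) with mild label noise."""
    records, truth = generate_county_dataset(
        SyntheticConfig(n_counties=12, seed=11))
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
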