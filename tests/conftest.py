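import numpy as np
import pytest

from bridgenet.mgm import MixedGraphicalModel
from bridgenet.synthetic import generate_dataset, small_scenario


@pytest.fixture(scope="session")
def small_model():
    return small_scenario()


@pytest.fixture(scope="session")
def small_data(small_model):
    """1200 subjects from the compact mixed scenario (complete data)."""
    data, table = generate_dataset(small_model, None, n=1200, seed=42)
    return data, table


@pytest.fixture(scope="session")
def small_results(small_data):
    data, _ = small_data
    return MixedGraphicalModel(data).fit()
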