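import numpy as np
import pytest

from ibfcc import BlockSpec, DataMatrix, generate_block_data


@pytest.fixture(scope="session")
def standard_block_data():
    """The standard planted fixture: C=3, 90x30, signal/background=10, sparsity 0.5."""
    spec = BlockSpec(C=3, seed=1)
    data, feat_labels = generate_block_data(spec)
    return data, feat_labels


@pytest.fixture()
def small_random_data():
    rng = np.random.default_rng(42)
    return DataMatrix(values=rng.uniform(0.1, 2.0, size=(6, 4)))
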