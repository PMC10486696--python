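import logging

import numpy as np
import pytest

logging.getLogger("holssa").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mi_set():
    """Default-condition motor-imagery benchmark set, generated once."""
    from holssa.synthetic import generate_mi_dataset

    return generate_mi_dataset(n_per_class=100, erd_depth=0.8, seed=0)
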