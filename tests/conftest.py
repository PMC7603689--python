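from dataclasses import replace

import numpy as np
import pytest

from negspace.synthetic_data import TINY, generate_dataset


@pytest.fixture(scope="session")
def tiny_data():
    """One tiny planted dataset shared across tests (seed 0)."""
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def tiny_datasets():
    """Factory for per-seed tiny datasets."""
    cache = {}

    def make(seed: int):
        if seed not in cache:
            cache[seed] = generate_dataset(replace(TINY, seed=seed))
        return cache[seed]

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
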