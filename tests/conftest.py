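import numpy as np
import pytest

import equiforms
from equiforms import (
    balance_by_swaps,
    initial_split,
    make_synthetic_bank,
)

# the library function is named like a test; tell pytest not to collect it
equiforms.test_information.__test__ = False
equiforms.grm_engine.test_information.__test__ = False


@pytest.fixture(scope="session")
def bank28():
    """A 28-item, 14-pair synthetic depression-style bank."""
    return make_synthetic_bank(28, 14, seed=7)


@pytest.fixture(scope="session")
def split28(bank28):
    """An information-balanced half-form split of the 28-item bank."""
    return balance_by_swaps(initial_split(bank28, seed=7), bank28)


@pytest.fixture(scope="session")
def bank8():
    """A small 8-item, 4-pair bank for cheap exhaustive checks."""
    return make_synthetic_bank(8, 4, seed=11)


def random_item(rng: np.random.Generator):
    """Draw a random valid GRM item for property checks."""
    from equiforms import ItemParameters

    a = rng.uniform(0.5, 4.0)
    b = np.sort(rng.uniform(-3.0, 3.0, size=4))
    for k in range(1, 4):
        if b[k] - b[k - 1] < 1e-3:
            b[k] = b[k - 1] + 1e-3
    return ItemParameters(f"r{rng.integers(1 << 30)}", float(a), tuple(float(x) for x in b))
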