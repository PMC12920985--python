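import numpy as np
import pytest


def random_mask_pairs(n_pairs, shape, seed, density=(0.05, 0.5)):
    """Seeded random mask pairs with densities drawn from `density`."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        p = rng.uniform(*density)
        q = rng.uniform(*density)
        pairs.append((rng.random(shape) < p, rng.random(shape) < q))
    return pairs


@pytest.fixture(scope="session")
def random_pairs_2d():
    return random_mask_pairs(50, (16, 16), seed=101)


@pytest.fixture(scope="session")
def random_pairs_3d():
    return random_mask_pairs(50, (8, 8, 8), seed=202)
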