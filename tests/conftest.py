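import numpy as np
import pytest

from rpvkit.synthetic import PhantomSpec, default_phantom, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """The shipped 64^3 phantom fixture (deterministic)."""
    return default_phantom()


@pytest.fixture(scope="session")
def phantom32():
    """A small phantom for fast extraction tests."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32), semi_axes=(10, 11, 9), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_level_grid(rng, max_side=6, max_ng=4):
    """A random small gray-level grid (0 = outside mask) with >= 2 levels."""
    while True:
        shape = tuple(rng.integers(2, max_side + 1, 3))
        ng = int(rng.integers(2, max_ng + 1))
        levels = rng.integers(0, ng + 1, shape)
        occupied = np.unique(levels[levels > 0])
        if len(occupied) >= 2:
            # relabel to 1..len(occupied) so every level in 1..ng is occupied
            remap = {v: i + 1 for i, v in enumerate(occupied)}
            out = np.zeros_like(levels)
            for v, i in remap.items():
                out[levels == v] = i
            return out, len(occupied)
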