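import numpy as np
import pytest

from carpreg import BinaryVolume, PhantomSpec, make_t_phantom


@pytest.fixture(scope="session")
def phantom() -> BinaryVolume:
    """Default t-shaped validation phantom (1152 voxels, 64^3 grid)."""
    return make_t_phantom(PhantomSpec())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)


def random_mask(rng: np.random.Generator, shape=(9, 9, 9), p: float = 0.3) -> BinaryVolume:
    """A random non-empty blob for oracle comparisons."""
    data = (rng.random(shape) < p).astype(np.uint8)
    if data.sum() == 0:
        data[tuple(s // 2 for s in shape)] = 1
    return BinaryVolume(data)
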