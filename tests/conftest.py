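import numpy as np
import pytest

from ldikit import NormalizedMatrix, load_packaged_scheme, load_packaged_scores


@pytest.fixture(scope="session")
def scheme():
    return load_packaged_scheme()


@pytest.fixture(scope="session")
def scores():
    return load_packaged_scores()


def random_block(rng: np.random.Generator, m: int, n: int) -> NormalizedMatrix:
    """A random normalized block: positive values, every column max = 100."""
    V = rng.uniform(1.0, 100.0, size=(m, n))
    V = V / V.max(axis=0) * 100.0
    return NormalizedMatrix(
        unit_ids=[f"u{i}" for i in range(m)],
        indicator_ids=[f"x{j}" for j in range(n)],
        values=V,
    )
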