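import numpy as np
import pytest

from sczeros import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 200-gene x 100-cell Poisson matrix with plenty of non-zeros."""
    return CountMatrix(rng.poisson(2.0, size=(200, 100)))


@pytest.fixture
def labeled_matrix(rng):
    """A small two-type matrix with distinct per-type gene means."""
    mus_a = rng.lognormal(0.0, 1.0, 60)
    mus_b = rng.lognormal(0.0, 1.0, 60)
    a = rng.poisson(mus_a[:, None], size=(60, 40))
    b = rng.poisson(mus_b[:, None], size=(60, 40))
    return CountMatrix(
        np.hstack([a, b]),
        cell_types=["A"] * 40 + ["B"] * 40,
    )
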