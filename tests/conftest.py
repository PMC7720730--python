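import numpy as np
import pytest

from mctbench import Dataset, fit_oneway


@pytest.fixture
def toy_dataset() -> Dataset:
    """Three small groups with means 2, 3, 7, within-group mean square 1."""
    return Dataset.from_groups([(1, 2, 3), (2, 3, 4), (6, 7, 8)])


@pytest.fixture
def toy_fit(toy_dataset):
    return fit_oneway(toy_dataset)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)


def random_dataset(
    gen: np.random.Generator,
    k: int | None = None,
    n: int | None = None,
    spread: float = 1.0,
    balanced: bool = True,
) -> Dataset:
    """A random normal dataset with group means drawn around zero."""
    k = k or int(gen.integers(3, 7))
    n = n or int(gen.integers(4, 12))
    sizes = [n] * k if balanced else [int(gen.integers(3, 2 * n)) for _ in range(k)]
    mus = gen.normal(0.0, spread, size=k)
    return Dataset.from_groups(
        [gen.normal(mu, 1.0, size=sz) for mu, sz in zip(mus, sizes)]
    )
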