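import numpy as np
import pytest

from contextfx import ContextCounts


@pytest.fixture
def worked_counts() -> ContextCounts:
    """The car-scenario participant: 30/20 target/competitor in context 1,
    10/15 in context 2, no decoy choices recorded."""
    return ContextCounts(30, 20, 0, 10, 15, 0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_counts(rng: np.random.Generator, equal_totals: bool = False,
                  max_n: int = 60) -> ContextCounts:
    """A random count table with at least one target/competitor choice per
    context; optionally with equal target+competitor totals across contexts."""
    n1 = int(rng.integers(1, max_n))
    n2 = n1 if equal_totals else int(rng.integers(1, max_n))
    t1 = int(rng.integers(0, n1 + 1))
    t2 = int(rng.integers(0, n2 + 1))
    d1, d2 = (int(v) for v in rng.integers(0, 10, size=2))
    return ContextCounts(t1, n1 - t1, d1, t2, n2 - t2, d2)
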