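import numpy as np
import pytest

from hdflow.events import EventStream


def random_stream(
    rng: np.random.Generator,
    n: int = 200,
    width: int = 16,
    height: int = 12,
    t_max: int = 10_000,
) -> EventStream:
    """A seeded random, time-sorted event stream for round-trip tests."""
    t = np.sort(rng.integers(0, t_max, size=n))
    x = rng.integers(0, width, size=n)
    y = rng.integers(0, height, size=n)
    p = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    return EventStream(width, height, t, x, y, p)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231115)
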