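import numpy as np
import pytest


@pytest.fixture
def ring5():
    """5x5 field: a one-pixel-thick ring at 0.9 on background 0.1.

    Its super-level barcode is known in closed form: one component bar
    (0.9, 0) and one loop bar (0.9, 0.1) — the loop fills when the interior
    pixel enters at p = 0.1.
    """
    f = np.full((5, 5), 0.1)
    f[1:4, 1:4] = 0.9
    f[2, 2] = 0.1
    return f


@pytest.fixture
def ring_with_gap():
    """9x9 thin ring at 0.9 with one ring pixel lowered to 0.4 (the gap)."""
    f = np.full((9, 9), 0.1)
    f[2:7, 2:7] = 0.9
    f[3:6, 3:6] = 0.1
    f[2, 4] = 0.4
    return f


def random_distinct_field(rng: np.random.Generator, shape) -> np.ndarray:
    """Uniform values in (0, 1), almost surely distinct with distinct gaps."""
    return rng.uniform(0.01, 0.99, size=shape)
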