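import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracle.py


@pytest.fixture
def alternating_window():
    """A 12-month reference window with mean 10 and population SD 4."""
    return [6.0, 14.0] * 6


def random_series(seed, n=40, allow_flat=False):
    """One seeded test series: noise around a base, sometimes with a shift."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(20, 80)
    sigma = rng.uniform(1, 12)
    x = rng.normal(base, sigma, n)
    kind = rng.integers(0, 3)
    if kind == 1:  # step
        at = rng.integers(14, n - 2)
        x[at:] += rng.uniform(-6, 6) * sigma
    elif kind == 2:  # ramp
        at = rng.integers(14, n - 4)
        x[at:] += np.linspace(0, rng.uniform(-8, 8) * sigma, n - at)
    return np.clip(x, 0, 100)
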