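import numpy as np
import pytest

from immunopet import PETVolume, PhantomSpec, SeedBox, ThresholdParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_phantom(seed: int, side: int = 16):
    """Small random blob phantom with a seed box around the hottest region."""
    rng = np.random.default_rng(seed)
    shape = (side,) * 3
    data = rng.gamma(2.0, 0.5, size=shape)
    center = rng.integers(side // 4, 3 * side // 4, size=3)
    grids = np.ogrid[0:side, 0:side, 0:side]
    r = rng.uniform(2.0, side / 5)
    rho2 = sum(((g - c) / r) ** 2 for g, c in zip(grids, center))
    data += rng.uniform(4, 10) * np.exp(-rho2)
    pad = int(np.ceil(r)) + 2
    lo = np.maximum(center - pad, 0)
    hi = np.minimum(center + pad + 1, side)
    box = SeedBox(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
    vol = PETVolume(data=data, spacing=(2.0, 2.0, 2.0))
    return vol, ThresholdParams(seed_box=box)


@pytest.fixture
def blob_phantom():
    return random_phantom(7)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-cached tiny phantom cohort for cross-module tests."""
    from immunopet import gen_phantom_cohort

    spec = PhantomSpec(n_patients=12, rng_seed=3)
    return spec, *gen_phantom_cohort(spec)
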