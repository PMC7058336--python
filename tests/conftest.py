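import numpy as np
import pytest

from assayerror import SyntheticConfig, generate_campaign, default_levels
from assayerror.profiles import PrecisionProfile


@pytest.fixture(scope="session")
def campaign():
    """Default study-condition campaign: 20 levels + blank, 24 specimens."""
    return generate_campaign(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_campaign():
    """Four levels + blank, 5 specimens — cheap enough for brute force."""
    cfg = SyntheticConfig(
        levels=[0.0, 0.1, 1.0, 10.0, 100.0],
        replicates_per_level=5,
        seed=7,
    )
    return generate_campaign(cfg)


@pytest.fixture()
def outlier_profile():
    """21-point profile from y = 0.01 + 0.05x with 5 tenfold outlier SDs."""
    x = np.array(default_levels(20))
    sd = 0.01 + 0.05 * x
    idx = np.random.default_rng(7).choice(len(x), 5, replace=False)
    sd[idx] *= 10
    return PrecisionProfile(tuple(x), tuple(sd), tuple([24] * len(x)))


def random_profile(rng, m):
    """A random, strictly increasing, positive-SD profile of m points.

    Levels are kept at least 2 concentration units apart, as in any real
    spiking design, which also keeps polynomial design matrices
    well-conditioned enough for tight oracle comparisons.
    """
    while True:
        x = np.sort(rng.uniform(0, 50, size=m))
        if m < 2 or np.min(np.diff(x)) > 2.0:
            break
    sd = rng.uniform(0.01, 5.0, size=m)
    return PrecisionProfile(tuple(x), tuple(sd), tuple([6] * m))
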