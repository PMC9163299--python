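import numpy as np
import pytest

from prebotpy.distribution_stats import bootstrap_null_dips, uniform_null_dips

#: gamma shape corresponding to the generator's default 10% period jitter
GAMMA_SHAPE = 100.0


@pytest.fixture(scope="session")
def gamma_null_table() -> np.ndarray:
    """Dip null table matched to the gamma interval distribution (n=60)."""
    return bootstrap_null_dips(
        60, 2000, seed=777, sampler=lambda rng, n: rng.gamma(GAMMA_SHAPE, 1.0, n)
    )


@pytest.fixture(scope="session")
def uniform_null_table() -> np.ndarray:
    """Classical uniform dip null table (n=60)."""
    return uniform_null_dips(60, 2000, seed=777)
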