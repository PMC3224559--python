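import numpy as np
import pytest

from surgekinetics import (
    RateSet,
    fit_capacity_model,
    haiti_observations,
)


@pytest.fixture(scope="session")
def haiti_fit():
    """The historical baseline fit (ka < kd branch), shared across tests."""
    return fit_capacity_model(haiti_observations())


@pytest.fixture(scope="session")
def fitted_rates(haiti_fit) -> RateSet:
    return haiti_fit.rates


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20211012)


def random_capacity_rates(rng: np.random.Generator) -> RateSet:
    """Well-conditioned random single-center rates: distinct ka/kd, and a
    throughput slow enough that t2 stays on a desk-scale horizon."""
    ka = rng.uniform(0.08, 1.2)
    kd = ka * rng.uniform(1.3, 6.0)
    k_prime = kd * rng.uniform(0.15, 0.9)
    return RateSet(ka=ka, kd=kd, k_prime=min(k_prime, 2.0))
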