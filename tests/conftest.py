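import numpy as np
import pytest

from bisir import (
    EpidemicParams,
    degenerate_distribution,
    poisson_degree_distribution,
    validate_params,
)


@pytest.fixture(scope="session")
def baseline_params() -> EpidemicParams:
    """The reference parameter set used throughout the worked examples."""
    return validate_params(b=0.08, d=0.05, beta=0.175, gamma=0.05, delta=0.2, lam=0.3, N=1)


@pytest.fixture(scope="session")
def dist_k4():
    return degenerate_distribution(4)


@pytest.fixture(scope="session")
def poisson_dist():
    return poisson_degree_distribution(4.0, 80)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240302)


def random_valid_params(rng: np.random.Generator, positive_death: bool = True):
    """Random parameter draw inside the valid domain (d bounded away from 0)."""
    return validate_params(
        b=float(rng.uniform(0.01, 0.5)),
        d=float(rng.uniform(0.01, 0.5)) if positive_death else 0.0,
        beta=float(rng.uniform(0.01, 1.0)),
        gamma=float(rng.uniform(0.01, 1.0)),
        delta=float(rng.uniform(0.0, 0.99)),
        lam=float(rng.uniform(0.0, 2.0)),
        N=1.0,
    )
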