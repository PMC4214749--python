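import numpy as np
import pytest

from netconsensus.netio import ParcellationScheme, WeightedNetwork
from netconsensus.synthgen import synthetic_scheme


@pytest.fixture
def scheme4() -> ParcellationScheme:
    return synthetic_scheme(4, name="tiny")


@pytest.fixture
def scheme10() -> ParcellationScheme:
    return synthetic_scheme(10, name="small")


@pytest.fixture
def scheme34() -> ParcellationScheme:
    return synthetic_scheme(34, name="common-scale")


def random_weighted(scheme: ParcellationScheme, rng: np.random.Generator,
                    zero_fraction: float = 0.0) -> WeightedNetwork:
    """Random valid weighted network: symmetric, non-negative, zero diagonal."""
    n = scheme.n_nodes
    iu = np.triu_indices(n, k=1)
    vals = rng.lognormal(0.0, 1.0, size=len(iu[0]))
    if zero_fraction:
        mask = rng.random(vals.size) < zero_fraction
        vals[mask] = 0.0
    w = np.zeros((n, n))
    w[iu] = vals
    return WeightedNetwork(scheme=scheme, weights=w + w.T)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
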