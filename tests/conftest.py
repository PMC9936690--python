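import pytest

import dgpbisect as dg

REFERENCE_SEED = 20230217


@pytest.fixture(scope="session")
def population_1m():
    """Frozen reference super-population: 5 standard normal + 5 Bernoulli(0.5), N=10^6."""
    return dg.generate_superpopulation(dg.CovariateSpec(5, 5, 0.5, 1_000_000), seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def population_100k():
    """Smaller super-population for monotonicity/attenuation property checks."""
    return dg.generate_superpopulation(dg.CovariateSpec(5, 5, 0.5, 100_000), seed=REFERENCE_SEED + 1)
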