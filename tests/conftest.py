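import numpy as np
import pytest

from coievol.simulate import BinCountDistribution, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 families x 5 BINs, no indels: shared by cheap structural tests."""
    cfg = SimConfig(
        n_families=20,
        bins_per_family=BinCountDistribution(5, 5, 0.0),
        indel_rate=0.0,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def indel_cohort():
    """50 families with ~30 planted indel events (rate 0.7/lineage)."""
    cfg = SimConfig(
        n_families=50,
        bins_per_family=BinCountDistribution(4, 4, 0.0),
        indel_rate=0.7,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
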