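import numpy as np
import pytest

from famgwas.simulate import SimulationConfig, simulate_random_mating


@pytest.fixture(scope="session")
def trio_dataset():
    """Mid-size trio cohort with direct and parental effects, used by several modules."""
    cfg = SimulationConfig(
        n_families=1500,
        n_snps=40,
        h2_direct=0.3,
        ige_coefficient=0.5,
        family_design={"trio": 1.0},
        seed=11,
    )
    return simulate_random_mating(cfg)


@pytest.fixture(scope="session")
def mixed_design_dataset():
    """Cohort mixing trios, sib pairs and single-parent duos."""
    cfg = SimulationConfig(
        n_families=1200,
        n_snps=30,
        h2_direct=0.3,
        ige_coefficient=0.0,
        family_design={"trio": 0.4, "sib_pair_no_parents": 0.4, "one_parent_duo": 0.2},
        seed=7,
    )
    return simulate_random_mating(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
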