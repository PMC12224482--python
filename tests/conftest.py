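import numpy as np
import pytest

from icedpy import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 sites x 150 participants, 2 regions, 1 measure; known components."""
    config = SimulationConfig(
        n_sites=3,
        n_per_site=150,
        regions=("regA", "regB"),
        measures=("thickness",),
        sigma_b2={"regA": 1.0, "regB": 2.0},
        sigma_e2=0.5,
        seed=42,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def multisite_dataset():
    """5 sites x 200, 4 regions, 2 measures — for map/pipeline level tests."""
    config = SimulationConfig(
        n_sites=5,
        n_per_site=200,
        regions=("r1", "r2", "r3", "r4"),
        measures=("thickness", "volume"),
        sigma_b2=1.0,
        sigma_e2=0.3,
        seed=7,
    )
    return generate_dataset(config)
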