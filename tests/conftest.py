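import numpy as np
import pytest

from phyllocom.simulate import SimulationConfig, generate_study
from phyllocom.tables import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    """Three samples x four ASVs with hand-readable counts."""
    return CountTable.from_arrays(
        ["s1", "s2", "s3"],
        ["a", "b", "c", "d"],
        np.array(
            [
                [5, 0, 3, 2],
                [0, 4, 1, 0],
                [2, 2, 2, 2],
            ]
        ),
    )


SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_asvs=250,
    n_replicates_per_cell=2,
    depth_range=(1084, 4000),
    n_drivers=5,
)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down synthetic study for fast integration tests."""
    return generate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_study():
    """The default-size synthetic study (full study conditions)."""
    return generate_study(SimulationConfig(seed=1))
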