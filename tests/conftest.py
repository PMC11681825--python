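import numpy as np
import pytest

from connstat.connectivity import BandDefinition
from connstat.simulate import SimulationConfig, simulate_fc_directly

ALPHA = BandDefinition("alpha", 8.0, 13.0)


@pytest.fixture(scope="session")
def small_null_cohort():
    """20-region, 4x12-subject null cohort drawn once per session."""
    cfg = SimulationConfig(
        group_sizes={"A": 12, "B": 12, "C": 12, "D": 12},
        n_regions=20,
        seed=11,
        bands=(ALPHA,),
    )
    return simulate_fc_directly(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
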