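import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hdbn import SimulationConfig, default_region_table, simulate_cohort


@pytest.fixture(scope="session")
def region_table():
    return default_region_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-effect cohort reused across statistical tests."""
    cfg = SimulationConfig(
        n_wt=8, n_ko=12, seed=42,
        planted_edges=tuple((a, b, 2.0) for a, b in [(1, 5), (37, 41)]),
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
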