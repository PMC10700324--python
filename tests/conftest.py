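import numpy as np
import pytest

from corrtf import CohortConfig, generate_cohort, load_region_table


@pytest.fixture(scope="session")
def table():
    return load_region_table()


@pytest.fixture(scope="session")
def small_null_cohort():
    """Tiny one-group cohort with no injected effects (8 regions)."""
    cfg = CohortConfig(group_sizes={"G": 6}, n_regions=8, n_timepoints=64,
                       tr_seconds=3.0, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
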