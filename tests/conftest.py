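import numpy as np
import pytest

from crossnet.extraction import RegionTimeSeriesSet
from crossnet.networks import load_network_table
from crossnet.synthetic import CohortSpec


@pytest.fixture(scope="session")
def networks():
    return load_network_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def small_ts(rng):
    """Random 40-timepoint series over 8 labelled regions."""
    labels = [f"r{i}" for i in range(8)]
    return RegionTimeSeriesSet("s01", labels, rng.standard_normal((40, 8)))


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """Reduced-region cohort used where full 84-region cohorts are overkill."""
    return CohortSpec(
        n_control=6,
        n_patient=6,
        n_regions_per_network={
            "MTN": 3, "DMN": 3, "SAN": 3, "STM": 6, "TEP": 3, "HIP": 2, "DAN": 3,
        },
        T=120,
        seed=11,
    )
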