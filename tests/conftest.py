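import numpy as np
import pytest

from scfc.simulate import CohortConfig, generate_cohort, records_to_manifest
from scfc.subnetworks import canonical_subnetworks


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A 21-subject cohort, fast enough for end-to-end unit tests."""
    return CohortConfig(
        n_per_group={"TDC": 7, "ADHD-I": 7, "ADHD-C": 7}, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, matrices = generate_cohort(small_config)
    return records, matrices


@pytest.fixture(scope="session")
def small_manifest(small_cohort):
    records, _ = small_cohort
    return records_to_manifest(records)


@pytest.fixture(scope="session")
def subnets():
    return canonical_subnetworks()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
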