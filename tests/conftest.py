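import pytest
from hypothesis import HealthCheck, settings

from surrotrial import SyntheticConfig, generate_dataset

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def paper_scale_records():
    """A seeded dataset at the scale of the real meta-analysis."""
    return generate_dataset(SyntheticConfig(seed=20240917))


@pytest.fixture()
def small_records():
    return generate_dataset(SyntheticConfig(k_trials=12, multi_arm_pairs=2,
                                            seed=11))
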