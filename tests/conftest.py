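import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def example_groups():
    """The worked two-group summary used throughout: dark 2.40+-0.80, light 2.25+-0.75."""
    from badgemeta.effect_sizes import GroupSummary

    return GroupSummary(mean_dark=2.40, mean_light=2.25, sd_dark=0.80,
                        sd_light=0.75, n_dark=10, n_light=10)


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic small multilevel dataset (k~25) for engine-level tests."""
    from badgemeta import synthetic_data as sd

    cfg = sd.SyntheticConfig(n_studies=12, n_species=8,
                             effects_per_study_range=(1, 3),
                             tree_seed=5, data_seed=6)
    dataset, truth = sd.simulate_r_scale_dataset(cfg)
    return dataset, truth
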