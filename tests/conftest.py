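import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dessound as ds

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def group_table() -> ds.GroupTable:
    return ds.GroupTable.builtin()


@pytest.fixture(scope="session")
def components() -> dict:
    return ds.load_components()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free databank from a fixed random 4-16-1 teacher network."""
    cfg = ds.SyntheticConfig(noise_sd=0.0, seed=7, teacher="network")
    return ds.generate_synthetic(cfg)


@pytest.fixture(scope="session")
def trained_model(noise_free_dataset):
    model, report = ds.train(noise_free_dataset, ds.TrainingConfig(seed=3))
    return model, report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
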