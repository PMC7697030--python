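import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beach_model():
    from littersim import beach_litter_lmc

    return beach_litter_lmc()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """A small calibrated truth field shared by fast tests."""
    from littersim import GridSpec, calibrated_model_and_specs, simulate_truth

    model, specs = calibrated_model_and_specs()
    grid = GridSpec(nx=20, ny=30)
    return simulate_truth(model, specs, grid, seed=7, n_lines=400)
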