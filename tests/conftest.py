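import pytest
from hypothesis import settings

from neurorelease import default_params, integrate_batch, integrate_cycle

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture():
    """The frozen default scenario."""
    return default_params()


@pytest.fixture(scope="session")
def batch_traj(fixture):
    """Default 60 s batch-reactor trajectory, 0.05 s output sampling."""
    return integrate_batch(fixture.batch_state0(), fixture.kinetics,
                           60.0, dt_out=0.05)


@pytest.fixture(scope="session")
def cycle_traj(fixture):
    """Default 600 s glutamate-cycle trajectory."""
    return integrate_cycle(fixture.cycle_state0(), fixture.cycle_params(),
                           600.0, dt_out=0.5)
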