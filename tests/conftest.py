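import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def library():
    from osteoquant import default_library

    return default_library()


@pytest.fixture(scope="session")
def small_scene():
    """A mixed scene (osteoclasts + precursors) small enough to render in
    well under a second, shared across read-only tests."""
    from osteoquant import SceneConfig, simulate_trajectories

    cfg = SceneConfig(
        field_size_px=(96, 96),
        n_frames=4,
        n_osteoclasts=4,
        r_type_fraction=0.5,
        n_precursors=6,
        photon_scale=None,
        seed=7,
    )
    return simulate_trajectories(cfg)
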