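import numpy as np
import pytest
from hypothesis import settings

from phaseopt.phantom import PhantomConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def small_config(**overrides) -> PhantomConfig:
    """Half-scale thorax on a 64^3 grid at 2 mm spacing: fast enough for
    unit tests while keeping every anatomical relation of the default."""
    params = dict(
        shape=(64, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        lung_semi_axes=(22.0, 30.0, 42.0),
        lung_center_right=(34.0, 64.0, 60.0),
        lung_center_left=(94.0, 64.0, 60.0),
        cord_radius=4.0,
        cord_center=(64.0, 98.0),
        tumor_semi_axes=(6.0, 6.0, 8.0),
        tumor_center=(36.0, 78.0, 55.0),
        amplitude_mm=8.0,
        ap_amplitude_mm=4.0,
        noise_sigma=10.0,
        seed=7,
    )
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    """(series, ground_truth) of the half-scale phantom, generated once."""
    return generate(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
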