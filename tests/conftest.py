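import numpy as np
import pytest

from podoquant import (
    SceneParams,
    calibrate_thresholds,
    generate_control_tile,
)


@pytest.fixture(scope="session")
def default_scene():
    return SceneParams()


@pytest.fixture(scope="session")
def ideal_scene():
    """Idealized rendering: no blur, no noise — measured values are exact."""
    return SceneParams(render_sigma_px=0.0, poisson_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_thresholds(default_scene):
    """Thresholds calibrated once from a noisy control tile."""
    return calibrate_thresholds(generate_control_tile(default_scene, 999))


@pytest.fixture(scope="session")
def ideal_thresholds(ideal_scene):
    """Thresholds from a noise-free control: exactly the channel backgrounds."""
    return calibrate_thresholds(generate_control_tile(ideal_scene, 999))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
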