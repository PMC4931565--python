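import numpy as np
import pytest

from cvtquant import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_scene():
    """A small, quiet scene for fast rendering tests."""
    return sim.SceneConfig(
        seed=7,
        image_shape=(9, 128, 128),
        n_cells=4,
        cell_radius=24.0,
    )


@pytest.fixture
def noise_free_scene():
    """Noise-free and tall enough that axial Gaussian tails are negligible."""
    return sim.SceneConfig(
        seed=7,
        image_shape=(21, 128, 128),
        n_cells=4,
        cell_radius=24.0,
        shot_noise=False,
        read_noise_sd=0.0,
    )


@pytest.fixture
def flat_noise_free_scene():
    """Noise-free with uniform background: isolates photon conservation of
    the measurement chain from background-model effects."""
    return sim.SceneConfig(
        seed=7,
        image_shape=(21, 128, 128),
        n_cells=4,
        cell_radius=24.0,
        shot_noise=False,
        read_noise_sd=0.0,
        cell_background=20.0,
        outside_background=20.0,
    )
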