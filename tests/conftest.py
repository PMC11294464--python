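import numpy as np
import pytest

import myobarcode as mb


@pytest.fixture(scope="session")
def small_population():
    """One myotome, 25 fibers, two time points, default FG conditions."""
    cfg = mb.SimulationConfig(seed=2, n_myotomes=1,
                              initial_fibers_per_myotome=25,
                              t_grid=(6.0, 8.0))
    frames, gt = mb.simulate_population(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def rendered_scene(small_population):
    """Noiseless render of the 25-fiber myotome at t = 6 dpf."""
    _, frames, _ = small_population
    f0 = frames[6.0]
    scene = mb.SceneSpec()
    img, labels, nuclei = mb.render_myotome_image(f0, scene, seed=3)
    return f0, scene, img, labels, nuclei


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
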