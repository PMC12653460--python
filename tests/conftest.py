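import numpy as np
import pytest

from octcalc.phantom import PhantomConfig, PlaqueSpec, generate_pullback


@pytest.fixture(scope="session")
def calcium_phantom():
    """Small seeded pullback with a single 90-degree, 1 mm calcium sector."""
    cfg = PhantomConfig(
        n_frames=3,
        n_alines=480,
        n_samples=256,
        radial_res_mm=0.01,
        lumen_radius_var=0.0,
        plaque_specs=(
            PlaqueSpec("calcium", arc_deg=90.0, thickness_mm=1.0, n_frames=3, center_deg=180.0),
        ),
        seed=7,
    )
    image, labels = generate_pullback(cfg)
    return cfg, image, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
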