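import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_scene():
    """A small unoccluded scene with known classes, rendered once."""
    from orchardet.synthetic_orchard import SceneSpec, render_scene

    spec = SceneSpec(
        image_size=128,
        n_fruits=6,
        radius_range=(7.0, 12.0),
        cluster_count=3,
        cluster_spread=30.0,
        occluder_density=0.0,
        seed=77,
    )
    image, truth = render_scene(spec)
    return spec, image, truth
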