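import numpy as np
import pytest

from goldpick.synthetic import SceneSpec, render_scene


@pytest.fixture(scope="session")
def flat_spec() -> SceneSpec:
    """Noise/blur/shadow-free flat-background scene, for pixel-count oracles."""
    return SceneSpec(
        height_px=128,
        width_px=128,
        counts_per_diameter=(0, 1),
        gradient_amplitude=0.0,
        shadow_count=0,
        noise_sigma=0.0,
        blur_sigma_px=0.0,
    )


@pytest.fixture(scope="session")
def flat_pair(flat_spec):
    return render_scene(flat_spec, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
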