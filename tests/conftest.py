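import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_patch_dataset():
    """24 labelled 96x96 patches shared across network tests."""
    from epistroma.synth import generate_patch_dataset

    return generate_patch_dataset(24, 96, 96, (0.2, 0.8), seed=11)


@pytest.fixture(scope="session")
def demo_slide():
    """One mid-sized synthetic slide with its ground truth."""
    from epistroma.synth import SlideSpec, generate_slide

    spec = SlideSpec(width_px=640, height_px=480, epi_fraction_target=0.55, seed=5)
    img, mask, achieved = generate_slide(spec)
    return spec, img, mask, achieved


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
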