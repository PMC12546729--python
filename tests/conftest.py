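import numpy as np
import pytest

from slidemil.preprocess import ResolutionLevel
from slidemil.synthetic import SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def level2():
    return ResolutionLevel(2)


@pytest.fixture(scope="session")
def tumour_slide():
    """512x512 tumour slide (30% tumour) with ground-truth mask."""
    spec = SyntheticSlideSpec(width_px=512, height_px=512,
                              class_label="tumour", tumour_area_fraction=0.30,
                              seed=7)
    img, mask, _ = generate_slide(spec)
    return img, mask, spec


@pytest.fixture(scope="session")
def normal_slide():
    spec = SyntheticSlideSpec(width_px=512, height_px=512, seed=11)
    img, mask, _ = generate_slide(spec)
    return img, mask, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
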