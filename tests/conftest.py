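import numpy as np
import pytest

from optonose.synth import canonical_scene, make_dye_library, render_array_image


@pytest.fixture(scope="session")
def library():
    return make_dye_library(0)


@pytest.fixture(scope="session")
def blank_image(library):
    return render_array_image(library, {}, canonical_scene(), seed=11)


@pytest.fixture(scope="session")
def exposed_image(library):
    return render_array_image(library, {"trans-2-hexenal": 200.0}, canonical_scene(), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
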