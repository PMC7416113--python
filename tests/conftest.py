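import numpy as np
import pytest

from chromarg.synthetic import make_kernel_template, make_noise_stimulus


@pytest.fixture(scope="session")
def stimulus():
    """Default 258 s binary noise stimulus, shared across tests."""
    return make_noise_stimulus(seed=1)


@pytest.fixture(scope="session")
def template_library():
    """Planted kernel templates spanning polarity, shape, and tempo."""
    lib = {}
    for pol in ("On", "Off"):
        for shape in ("monophasic", "biphasic"):
            for tc in (0.08, 0.12, 0.16):
                lib[(pol, shape, tc)] = make_kernel_template(
                    pol, shape, tc, (1.0, 0.7, 0.3, 0.5))
    return lib


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
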