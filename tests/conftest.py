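import numpy as np
import pytest

from zslice.network import NetConfig, init_student_params, zero_like_params
from zslice.augment_z import InterpolatorModel
from zslice.phantoms import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reduced_config():
    return NetConfig.reduced_profile(input_size=64)


@pytest.fixture(scope="session")
def zero_model(reduced_config):
    """Reduced-profile interpolator with all weights zero: its prediction is
    analytically the plane average (flows 0, mask 1/2)."""
    params = zero_like_params(init_student_params(reduced_config))
    return InterpolatorModel(student=params, net_config=reduced_config)


@pytest.fixture(scope="session")
def shell_stack():
    """Small membrane-shell phantom stack (9 anisotropic slices, 64x64)."""
    spec = PhantomSpec(kind="shell", size=64, n_slices=9, dz=4.0, radius=20.0, noise_sigma=3.0, seed=3)
    stack, _ = make_phantom(spec)
    return stack
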