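import numpy as np
import pytest

from qlsm.phantom import PhantomSpec, generate_phantom

SMALL_KW = dict(
    volume_shape_vox=(32, 96, 96),
    shell_thickness_um=30.0,
    layer_thickness_um=12.0,
    shell_curvature=0.0,
)


def small_spec(**overrides) -> PhantomSpec:
    kw = {**SMALL_KW, **overrides}
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """A small default-noise phantom shared across tests."""
    spec = small_spec(coupling_rho=0.5, rng_seed=7)
    channels, gt = generate_phantom(spec)
    return spec, channels, gt


@pytest.fixture(scope="session")
def small_phantom_noise_free():
    spec = small_spec(
        coupling_rho=0.5, rng_seed=7, noise_gaussian_sd=0.0, noise_poisson_scale=0.0, background_gradient=0.0
    )
    channels, gt = generate_phantom(spec)
    return spec, channels, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
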