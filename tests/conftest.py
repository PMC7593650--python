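import numpy as np
import pytest

from kneefem.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def coarse_spec():
    """Phantom at 34.8 um spacing: fast enough for per-test image checks."""
    return PhantomSpec(voxel_spacing_um=34.8, seed=7)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    return generate_phantom(coarse_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom for geometric oracles."""
    spec = PhantomSpec(voxel_spacing_um=34.8, noise_sd=0.0, seed=3)
    return spec, generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
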