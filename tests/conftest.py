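import hypothesis
import numpy as np
import pytest

from octbga import run_segment
from octbga.phantom import PhantomSpec, generate_phantom
from octbga.preprocess import OctVolume

hypothesis.settings.register_profile(
    "octbga", derandomize=True, deadline=None,
    suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("octbga")


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    """Default phantom rendered without noise or shadows: (volume, truth)."""
    return generate_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def segmented(noise_free_spec, noise_free_phantom):
    """Full pipeline result on the noise-free default phantom."""
    volume, _ = noise_free_phantom
    return run_segment(volume, noise_free_spec.reference_profile())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_volume(rng: np.random.Generator, shape=(8, 8, 8)) -> OctVolume:
    return OctVolume(data=rng.integers(0, 256, shape).astype(np.uint8))
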