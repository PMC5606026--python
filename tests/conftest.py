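import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinefuse.phantom import PhantomConfig, generate_atlas_set, generate_spine_phantom

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def coarse_case():
    """A default-condition phantom on the compact test geometry."""
    return generate_spine_phantom(PhantomConfig.coarse(seed=1))


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free phantom with modest warp and motion (compact geometry)."""
    return generate_spine_phantom(PhantomConfig.coarse(seed=5, noise_sd=0.0))


@pytest.fixture(scope="session")
def still_case():
    """Phantom with no motion, no warp, no noise: TP2 differs from TP1 only at lesions."""
    return generate_spine_phantom(
        PhantomConfig.coarse(
            seed=2,
            global_warp_amplitude_mm=0.0,
            max_rotation_deg=0.0,
            max_translation_mm=0.0,
            noise_sd=0.0,
        )
    )


@pytest.fixture(scope="session")
def atlas_set():
    """An 11-patient atlas set on the compact geometry."""
    return generate_atlas_set(11, PhantomConfig.coarse(), seed=1000)


@pytest.fixture(scope="session")
def coarse_vus(coarse_case):
    from spinefuse.segmentation import build_vertebral_units

    return build_vertebral_units(coarse_case.mask_tp1)
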