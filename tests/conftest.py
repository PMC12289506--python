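import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from habitatpipe.phantom import (
    ClinicalRecord,
    GroundTruth,
    PatientCase,
    PhantomConfig,
    generate_phantom,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ZERO_SDS = ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))


@pytest.fixture(scope="session")
def default_case():
    """One phantom at default noise/geometry."""
    return generate_phantom(PhantomConfig(seed=11), 0)


@pytest.fixture(scope="session")
def zero_noise_case():
    """Noiseless phantom: every ROI voxel sits exactly on a habitat mean."""
    return generate_phantom(PhantomConfig(seed=5, habitat_intensity_sds=ZERO_SDS), 0)


@pytest.fixture(scope="session")
def small_config():
    """Cheap geometry for cohort-scale contract tests."""
    return PhantomConfig(seed=3, grid_size=32, radius_range=(5.0, 9.0))


def make_clinical(rng: np.random.Generator) -> ClinicalRecord:
    from habitatpipe.phantom import _sample_clinical

    return _sample_clinical(rng)


def make_dummy_case(i: int, fractions, clinical=None) -> PatientCase:
    """Volume-free case carrying only what the label model consumes."""
    return PatientCase(
        id=f"dummy{i:04d}",
        t2=None,
        adc=None,
        mask=None,
        clinical=clinical,
        truth=GroundTruth(habitat_labels=None, fractions=np.asarray(fractions, float)),
    )
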