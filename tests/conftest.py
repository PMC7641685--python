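import numpy as np
import pytest

from mammocad.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def noisefree_phantom():
    """One deterministic noise-free left-sided phantom with a bright lesion."""
    spec = PhantomSpec(noise_sd=0, has_lesion=True, lesion_intensity=255,
                       lesion_radius=14)
    return generate_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def noisefree_cohort_50():
    """50 noise-free phantoms (20 normal / 15 benign / 15 malignant)."""
    spec = CohortSpec(n_normal=20, n_benign=15, n_malignant=15, seed=11,
                      noise_sd=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
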