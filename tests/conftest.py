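import numpy as np
import pytest

from cefpk import CohortDesign, SAEMSettings, simulate_dataset
from cefpk.reference import final_model


@pytest.fixture(scope="session")
def model():
    """The final 2-compartment cefazolin model with its published estimates."""
    return final_model()


@pytest.fixture(scope="session")
def study_dataset(model):
    """One 100-subject synthetic dataset under the study design."""
    return simulate_dataset(model, CohortDesign(n_subjects=100), seed=20250901)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced SAEM settings for tests that fit many models."""
    return SAEMSettings(n_exploration=150, n_smoothing=100, ll_samples=1000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
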