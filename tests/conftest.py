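import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msipredict import CohortSpec, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")
from msipredict.preprocess import detect_and_align_peaks, preprocess


@pytest.fixture(scope="session")
def mini_cohort():
    """Small synthetic cohort shared by the fast unit tests."""
    spec = CohortSpec(
        cohort_id="CDDP",
        n_patients_per_class=(5, 4),
        spectra_per_patient=(30, 40),
        n_features=60,
        n_signal_features=8,
        effect_size=1.2,
        slide_count=2,
        seed=42,
    )
    data, truth = generate_cohort(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def mini_features(mini_cohort):
    _, data, _ = mini_cohort
    prepared = preprocess(data, structure_width=5)
    return detect_and_align_peaks(prepared, tolerance=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
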