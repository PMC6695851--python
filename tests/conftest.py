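import numpy as np
import pytest

from avfppg import hemodynamics as hd
from avfppg.classify.features import FeatureVector, LabeledSubject
from avfppg.synthetic_data import CohortSpec, WaveformSpec, sample_cohort, sample_waveform


@pytest.fixture(scope="session")
def calibration() -> hd.CalibrationConstants:
    return hd.CalibrationConstants()


@pytest.fixture(scope="session")
def fixture_vessel_params() -> dict:
    """Regression fixture: mid-sized vessel at 72 bpm."""
    return {
        "d0": 0.5,
        "h": 0.05,
        "E": 4.0e6,
        "sigma_p": 0.49,
        "sbp": 120.0,
        "dbp": 80.0,
        "hr_bpm": 72.0,
    }


@pytest.fixture(scope="session")
def clean_cohort() -> list[LabeledSubject]:
    """Noise-free cohort used by closure tests (session-scoped, cheap)."""
    return sample_cohort(CohortSpec(n_subjects=50, seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort() -> list[LabeledSubject]:
    return sample_cohort(CohortSpec(n_subjects=60, seed=7, noise_sd=0.02))


@pytest.fixture()
def constant_pi_subject() -> LabeledSubject:
    fv = FeatureVector(
        pi_max=0.02 * (1 + 1e-9), pi_min=0.02, spo2=0.97, sbp=120, dbp=80, hr=72
    )
    return LabeledSubject("CONST", fv, dos_label=1, bfv_label=1)


@pytest.fixture()
def clean_waveform(constant_pi_subject):
    w, truth = sample_waveform(constant_pi_subject, WaveformSpec(seed=0))
    return w, truth
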