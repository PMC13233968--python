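import numpy as np
import pytest

from pedqtc.synthcohort import (GeneratorParams, SubjectProfile,
                                synthesize_ecg)


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(patient_id="P000000", age_years=8.0, sex="male",
                          race="white")


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, wander-free generator settings with constant RR."""
    return GeneratorParams(noise_sd_mv=0.0, wander_amp_mv=0.0, rr_cv=0.0,
                           seed=0)


def make_record(subject, params, qt_ms=400.0, rr_ms=600.0, n_beats=None,
                rr_seq=None, rng=None):
    if rr_seq is None:
        if n_beats is None:
            n_beats = int(np.ceil(10800.0 / rr_ms)) + 2
        rr_seq = np.full(n_beats, float(rr_ms))
    return synthesize_ecg((subject, float(qt_ms), rr_seq), params, rng=rng)


@pytest.fixture(scope="session")
def clean_record(subject, clean_params):
    """One deterministic noise-free record: QT 400 ms, RR 600 ms."""
    return make_record(subject, clean_params)
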