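"""Shared fixtures: small, fast synthetic cohorts (generated at run time)."""

import numpy as np
import pytest

from effortlab import preprocessing
from effortlab.synthetic_cohort import (CohortCoupling, ParticipantProfile,
                                        TaskDesign, generate_cohort)


@pytest.fixture(scope="session")
def fast_design():
    """Default task design with traces downsampled to 50 Hz for speed."""
    return TaskDesign(sample_rate_hz=50.0)


@pytest.fixture(scope="session")
def small_cohort(fast_design):
    """12 simulated participants with the miscalibration bug active."""
    return generate_cohort(12, design=fast_design, seed=42)


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    retained, report = preprocessing.preprocess_cohort(small_cohort)
    return retained, report


@pytest.fixture(scope="session")
def feature_matrices(preprocessed):
    from effortlab.trace_features import build_cohort_features

    retained, _ = preprocessed
    return build_cohort_features(retained)


def make_profile(**overrides) -> ParticipantProfile:
    """A deterministic, hand-built participant profile for unit tests."""
    defaults = dict(
        id="T001", age=28.0, sex=0, dominant_hand="right",
        mvc_dom=400.0, mvc_nondom=300.0, latent_symptom=0.0,
        phq9=6, aes=31, rating_intercept=10.0,
        force_sensitivity_true=60.0, failure_sensitivity_true=5.0,
        motor_noise_scale=0.13, rating_noise_sd=7.0, capacity=1.0,
    )
    defaults.update(overrides)
    return ParticipantProfile(**defaults)


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def quiet_profile():
    """Noise-free profile: deterministic traces and ratings."""
    return make_profile(motor_noise_scale=0.0, rating_noise_sd=0.0,
                        overshoot_mean=0.0, overshoot_sd=0.0,
                        w_overshoot=0.0, w_cumulative=0.0, w_cv=0.0,
                        w_excess=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
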