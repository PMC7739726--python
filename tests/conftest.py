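import pytest

from skicap import TestConditions
from skicap.io import cohort_to_frames, estimate_cohort_frames
from skicap.simulate import ds_scenario, generate_cohort


@pytest.fixture
def dp_conditions():
    """Double-poling test conditions with the study's group-mean masses."""
    return TestConditions(incline_deg=1.5, mu_r=0.0215, body_mass_kg=77.3, system_mass_kg=80.7)


@pytest.fixture
def ds_conditions():
    return TestConditions(incline_deg=6.5, mu_r=0.0215, body_mass_kg=77.3, system_mass_kg=80.7)


@pytest.fixture
def flat_conditions():
    """Level treadmill, rolling resistance only."""
    return TestConditions(incline_deg=0.0, mu_r=0.0215, body_mass_kg=77.0, system_mass_kg=80.0)


@pytest.fixture(scope="session")
def noiseless_ds_frames():
    """A small noiseless diagonal-stride cohort as tidy tables + estimates."""
    cohort = generate_cohort(ds_scenario(n=4, stage_noise_sd=0.0), seed=7)
    frames = cohort_to_frames(cohort)
    frames["estimates"] = estimate_cohort_frames(frames["stages"], frames["tt"], frames["athletes"])
    return frames
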