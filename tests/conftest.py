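import dataclasses

import pytest

from bexcess import StudyDesign, generate_study, volunteer_study_design


def noiseless_design(**overrides) -> StudyDesign:
    """Volunteer-like design with every randomness source switched off."""
    base = dict(
        study_id="noiseless",
        beta_true_sd=0.0,
        baseline_sbe_sd=0.0,
        ph_noise_sd=0.0,
        pco2_noise_sd=0.0,
        seed=0,
    )
    base.update(overrides)
    return StudyDesign(**base)


@pytest.fixture(scope="session")
def volunteer_dataset():
    """One default-noise volunteer-like dataset (14 subjects x 4 levels)."""
    return generate_study(volunteer_study_design(seed=2024))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise dataset at beta_true = 12.1 for exact-recovery checks."""
    return generate_study(noiseless_design())


def design_variant(design: StudyDesign, **overrides) -> StudyDesign:
    return dataclasses.replace(design, **overrides)
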