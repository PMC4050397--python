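import pandas as pd
import pytest

from ssi_ident.claims_model import PatientEpisode, episodes_to_frame


@pytest.fixture
def two_episode_frame() -> pd.DataFrame:
    """Two hand-built episodes, one per class, with known field values."""
    episodes = [
        PatientEpisode(
            patient_id="A", age=60, sex="male", los=10.0, vessels_obstructed=2,
            antibiotic_types=1, antibiotic_ddd_total=4.0, cefazolin_ddd=4.0,
            atc_codes_used={"J01DB04"}, ssi_label=0,
        ),
        PatientEpisode(
            patient_id="B", age=70, sex="female", los=50.0, vessels_obstructed=1,
            antibiotic_types=5, antibiotic_ddd_total=30.0, cefazolin_ddd=0.0,
            atc_codes_used={"J01XA01"}, index_secondary_dx={"998.5"}, ssi_label=1,
        ),
    ]
    return episodes_to_frame(episodes)


@pytest.fixture(scope="session")
def center_a_cohort() -> pd.DataFrame:
    """One seeded training-size synthetic cohort, shared across tests."""
    from ssi_ident.synthetic_cohort import center_a_spec, generate_cohort

    return generate_cohort(center_a_spec(seed=11)).frame
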