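import pytest

from csia_tp import DEFAULT_FRAMEWORKS, AminoAcidProfile, make_study_fixture

BOWHEAD_SKIN_MEANS = {
    "Glx": 19.02,
    "Asx": 13.91,
    "Ala": 17.03,
    "Ile": 17.42,
    "Leu": 15.24,
    "Pro": 19.41,
    "Val": 19.29,
    "Gly": 8.18,
    "Phe": 5.53,
}


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture()


@pytest.fixture(scope="session")
def study_profiles(study_fixture):
    return study_fixture[0]


@pytest.fixture(scope="session")
def study_deltas(study_fixture):
    return study_fixture[1]


@pytest.fixture(scope="session")
def frameworks():
    return DEFAULT_FRAMEWORKS


@pytest.fixture()
def bowhead_skin_profile():
    """Group-mean bowhead skin profile with all nine measured amino acids."""
    return AminoAcidProfile(
        specimen_id="bw-skin-mean",
        species="bowhead_whale",
        tissue="skin",
        aa_d15n=dict(BOWHEAD_SKIN_MEANS),
    )
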