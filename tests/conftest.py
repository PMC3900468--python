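import pytest

from anuadri import Participant, build_scorecard


@pytest.fixture(scope="session")
def map_card():
    return build_scorecard("anu_adri_map")


@pytest.fixture(scope="session")
def cvhs_card():
    return build_scorecard("anu_adri_cvhs")


@pytest.fixture(scope="session")
def kp_card():
    return build_scorecard("anu_adri_kp")


@pytest.fixture(scope="session")
def full_card():
    return build_scorecard("anu_adri_full")


@pytest.fixture
def high_risk_woman():
    """Worked example: 87-year-old woman with every MAP risk factor at its
    reference-or-risk level (expected MAP score 35+0+3+4+0+6+0+0+0 = 48)."""
    return Participant(
        id="w87", sex="female", age_years=87,
        factor_values={
            "education": "<8", "diabetes": "yes", "tbi": "yes",
            "cognitive_activity": "low", "social_network": "low",
            "smoking": "never", "alcohol": "abstainer",
            "physical_activity": "low",
        },
    )


@pytest.fixture
def low_risk_man():
    """Worked example: 63-year-old man with every protective level
    (expected MAP score 0+6+0+0-7+0+0-3-3 = -7)."""
    return Participant(
        id="m63", sex="male", age_years=63,
        factor_values={
            "education": ">11", "diabetes": "no", "tbi": "no",
            "cognitive_activity": "high", "social_network": "high",
            "smoking": "never", "alcohol": "light_moderate",
            "physical_activity": "high",
        },
    )
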