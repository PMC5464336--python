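import pytest

from teapbpk import DoseEvent, load_model, simulate


@pytest.fixture(scope="session")
def human_egcg_model():
    """Human EGCg model for the 600 mg PE mixture study (72 kg)."""
    return load_model("EGCg", "human", 72.0, "chow2003")


@pytest.fixture(scope="session")
def human_egcg_dose():
    return DoseEvent("EGCg", 8.3)


@pytest.fixture(scope="session")
def human_egcg_result(human_egcg_model, human_egcg_dose):
    return simulate(human_egcg_model, human_egcg_dose, t_end=24.0)


@pytest.fixture(scope="session")
def rat_egcg_model():
    return load_model("EGCg", "rat", 0.26)
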