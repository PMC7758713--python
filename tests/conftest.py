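import numpy as np
import pytest

from twentyq import Scene, build_model, run_scenario, run_violation


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def true_scene():
    return Scene()  # green square above, red square below


@pytest.fixture(scope="session")
def solo_result():
    return run_scenario({"scenario": "solo", "seed": 1})


@pytest.fixture(scope="session")
def dyad_result():
    return run_scenario({"scenario": "dyad_qa", "seed": 1})


@pytest.fixture(scope="session")
def role_reversal_result():
    return run_scenario({"scenario": "role_reversal", "seed": 1})


@pytest.fixture(scope="session")
def folie_default_result():
    return run_scenario({"scenario": "folie_a_deux", "seed": 1, "true_scene": None})


@pytest.fixture(scope="session")
def folie_zero_result():
    return run_scenario(
        {
            "scenario": "folie_a_deux",
            "seed": 1,
            "true_scene": None,
            "not_sure_likelihood": 0.0,
        }
    )


@pytest.fixture(scope="session")
def violation_result():
    return run_violation({"seed": 1})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
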