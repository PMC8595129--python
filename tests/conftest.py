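import numpy as np
import pytest

from lipopbpk.pbpk import DoseEvent, simulate
from lipopbpk.physiology import load_physiology
from lipopbpk.synthetic import monkey_truth_model, species_truth_model


@pytest.fixture(scope="session")
def monkey_phys():
    return load_physiology("monkey")


@pytest.fixture(scope="session")
def monkey_truth():
    """Monkey whole-body model at 100 ml/kg/h clearance (0.6 L/h at 6 kg)."""
    return monkey_truth_model(100.0)


@pytest.fixture(scope="session")
def human_model_4Lh():
    """60 kg human model with the reported systemic clearance of 4 L/h."""
    return species_truth_model("human_chinese_male", 4.0)


@pytest.fixture(scope="session")
def monkey_sim_69mg(monkey_truth):
    """11.5 mg/kg x 6 kg bolus simulated over 12 h (dense grid)."""
    model = monkey_truth.with_dosing([DoseEvent("iv_bolus", 69.0, 0.0)])
    return simulate(model, 12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20211103)
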