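import numpy as np
import pytest

from pulsecode import PsychModel, PulseSpec, TrainSpec, make_train
from pulsecode.stimuli import RANGE_I, RANGE_II
from pulsecode.synth import SyntheticParticipant, make_design, simulate_responses

ANCHOR_I = (RANGE_I.ref_amplitude, RANGE_I.ref_width)  # (40 μm, 5.882 ms)
ANCHOR_II = (RANGE_II.ref_amplitude, RANGE_II.ref_width)  # (100 μm, 28.571 ms)


@pytest.fixture(scope="session")
def reference_train_i() -> np.ndarray:
    return make_train(TrainSpec(PulseSpec(*ANCHOR_I), RANGE_I.ref_rate))


@pytest.fixture(scope="session")
def reference_train_ii() -> np.ndarray:
    return make_train(TrainSpec(PulseSpec(*ANCHOR_II), RANGE_II.ref_rate))


@pytest.fixture(scope="session")
def shape_design_i():
    return make_design("shape", "I", "d")


@pytest.fixture(scope="session")
def session_trials(shape_design_i):
    """One simulated shape-change session from a known observer."""
    observer = SyntheticParticipant(
        "S01", PsychModel(threshold=1.1, width=0.3, guess=0.1, lapse=0.03), seed=42
    )
    return observer, simulate_responses(observer, shape_design_i)
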