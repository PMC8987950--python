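import numpy as np
import pytest

from gradedreach import Anthropometry, ParticipantModel


@pytest.fixture
def anthro() -> Anthropometry:
    return Anthropometry(hip_height=0.95, trunk_length=0.48, arm_length=0.72)


@pytest.fixture
def participant(anthro) -> ParticipantModel:
    return ParticipantModel(anthro=anthro)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
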