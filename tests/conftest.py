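import numpy as np
import pytest

from affatp import CriticParams, CriticState, run_conditioning_trial
from affatp.schedules import TrialTiming


@pytest.fixture
def timing():
    return TrialTiming()


@pytest.fixture
def params():
    return CriticParams()


@pytest.fixture
def train_critic(timing, params):
    """Factory: train a fresh single-stimulus critic on Bernoulli(lam) reward."""

    def _train(lam, n_trials=500, seed=0, record_from=None, p=params):
        rng = np.random.default_rng(seed)
        state = CriticState(stimuli=("S",), n_taps=timing.n_steps)
        tail = []
        for i in range(n_trials):
            reward = 1.0 if rng.random() < lam else 0.0
            run_conditioning_trial(state, p, "S", reward, timing)
            if record_from is not None and i >= record_from:
                tail.append(
                    (state.peak_magnitude("S"), state.omission_value("S"))
                )
        return state, tail

    return _train
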