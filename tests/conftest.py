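import numpy as np
import pandas as pd
import pytest

from timeprior import ObserverParams, build_paradigm, simulate_reproduction


@pytest.fixture(scope="session")
def paradigm():
    return build_paradigm()


@pytest.fixture(scope="session")
def default_observer():
    """The canonical broad-prior / low-resolution observer."""
    return ObserverParams(prior_width_ms=400.0, weber_fraction=0.36)


@pytest.fixture(scope="session")
def short_session_trials(paradigm, default_observer):
    return simulate_reproduction(default_observer, paradigm.short_session, seed=123)


def veridical_trials(durations, trials_per_duration=7, session="short"):
    """Noise-free trials reproducing each stimulus exactly."""
    stim = np.repeat(np.asarray(durations, dtype=float), trials_per_duration)
    return pd.DataFrame(
        {
            "session": session,
            "trial_index": np.arange(stim.size),
            "stimulus_ms": stim,
            "reproduced_ms": stim.copy(),
        }
    )
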