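import numpy as np
import pytest

from graspcode import TaskConfig, generate_trials, make_population, simulate_spikes


@pytest.fixture(scope="session")
def small_trials():
    """20 trials (5 per condition), fixed seed."""
    return generate_trials(TaskConfig(n_trials_per_condition=5, seed=11))


@pytest.fixture(scope="session")
def small_session(small_trials):
    """Trials + spikes for a 6-unit mixed population."""
    pop = make_population(n_grip_only=2, n_mixed=2, n_force_only=1, n_null=1, seed=12)
    spikes = simulate_spikes(small_trials, pop, seed=13)
    return small_trials, spikes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def grip_positive(trials) -> np.ndarray:
    return trials["grip"].to_numpy() == "side"


def force_positive(trials) -> np.ndarray:
    return trials["force"].to_numpy() == "high"
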