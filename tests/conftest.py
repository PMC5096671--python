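import numpy as np
import pytest

from reachdyn.dynamical import simulate_dynamical
from reachdyn.representational import (
    RepresentationalParams,
    detect_neural_movement_onset,
    simulate_representational,
)
from reachdyn.rnn import TrainingConfig, export_population, init_network, make_trials, train
from reachdyn.task import make_targets


@pytest.fixture(scope="session")
def task13():
    return make_targets(13)


@pytest.fixture(scope="session")
def task6():
    return make_targets(6)


@pytest.fixture(scope="session")
def repr_pop(task13):
    """Full-size cosine-tuned population at the headline parameters."""
    pop = simulate_representational(RepresentationalParams(), task13, seed=0)
    detect_neural_movement_onset(pop)
    return pop


@pytest.fixture(scope="session")
def dyn_pop(task13):
    """Full-size two-oscillator population."""
    return simulate_dynamical(task13, seed=0)


@pytest.fixture(scope="session")
def small_repr_pop(task6):
    """30-neuron population for fast permutation-test checks."""
    pop = simulate_representational(
        RepresentationalParams(n_neurons=30), task6, seed=7
    )
    detect_neural_movement_onset(pop)
    return pop


@pytest.fixture(scope="session")
def trained_rnn(task13):
    """One trained full-size network, shared by all RNN-dependent tests."""
    cfg = TrainingConfig(max_iter=500)
    model = init_network(n_units=200, seed=0)
    trials = make_trials(task13, cfg)
    trained, info = train(model, trials, cfg)
    return trained, trials, info


@pytest.fixture(scope="session")
def rnn_pop(trained_rnn):
    trained, trials, _ = trained_rnn
    return export_population(trained, trials, delay=800.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
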