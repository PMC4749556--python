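import numpy as np
import pytest

from metabet import (
    ExperimentDesign,
    ObserverConfig,
    default_observer_config,
    simulate_dataset,
    subject_curve,
)


@pytest.fixture(scope="session")
def design():
    """Reference full design: 13 contrasts, 2600 trials, 200 per contrast."""
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_design():
    """One-session design for fast CSV / CLI tests (104 trials)."""
    return ExperimentDesign(trials_per_cell=2, n_sessions=1)


@pytest.fixture(scope="session")
def ideal_agent(design):
    """Noiseless Bayesian observer marginalising over the design's grid."""
    return default_observer_config(design, seed=11)


@pytest.fixture(scope="session")
def ideal_dataset(design, ideal_agent):
    """One simulated ideal-observer subject run through the full design."""
    return simulate_dataset(design, ideal_agent, seed=101, subject_id="ideal01")


@pytest.fixture(scope="session")
def ideal_curve(ideal_dataset):
    return subject_curve(ideal_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
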