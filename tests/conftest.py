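import warnings

import numpy as np
import pytest

from simonstop.design import DesignConfig, generate_trial_sequence
from simonstop.eegsim import EEGSimSpec, generate_epochs
from simonstop.race import RaceModelParams, simulate_subject


@pytest.fixture(autouse=True)
def _quiet_nonconvergence_warnings():
    # non-converged RIDE runs are a legitimate outcome on noisy data; the
    # warning itself is tested explicitly where relevant
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="RIDE latency estimation did not converge")
        yield


@pytest.fixture
def design_config():
    return DesignConfig()


@pytest.fixture
def race_params():
    return RaceModelParams()


@pytest.fixture(scope="session")
def full_session():
    """One subject simulated through the complete 936-trial session."""
    cfg = DesignConfig()
    params = RaceModelParams()
    seq = generate_trial_sequence(cfg, seed=11)
    records, staircase = simulate_subject(params, seq, cfg, seed=11)
    return cfg, seq, records, staircase


@pytest.fixture(scope="session")
def small_epoch_set():
    """Epochs for a 1-block session (fast shared fixture)."""
    cfg = DesignConfig(n_blocks=1)
    params = RaceModelParams()
    seq = generate_trial_sequence(cfg, seed=5)
    records, _ = simulate_subject(params, seq, cfg, seed=5)
    spec = EEGSimSpec()
    epochs, truth = generate_epochs(spec, records, seed=5)
    return spec, records, epochs, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
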