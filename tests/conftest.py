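import numpy as np
import pytest

from rtnf import build_paradigm, make_subject_profile, simulate_run
from rtnf.experiment import default_config, train_tutor_model


@pytest.fixture(scope="session")
def paradigm():
    return build_paradigm()


@pytest.fixture(scope="session")
def trained_setup():
    """One tutor model trained on the default study-like configuration.

    Returns (config, model, cv_report, norm_params); shared across tests
    because training simulates and preprocesses four full runs.
    """
    cfg = default_config(master_seed=1, n_patients=1)
    model, report, norm = train_tutor_model(cfg)
    return cfg, model, report, norm


@pytest.fixture(scope="session")
def quiet_run(paradigm):
    """A noiseless, driftless, zero-amplitude run: every volume == baseline."""
    profile = make_subject_profile(
        pattern_fidelity=1.0, seed=0, amplitude=0.0,
        noise_sigma=0.0, drift_amplitude=0.0,
    )
    return simulate_run(paradigm, profile, seed=0), profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
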