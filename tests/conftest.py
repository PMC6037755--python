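import numpy as np
import pytest

from attnvar.stimulus import ScheduleConfig, StimulusParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stim_params():
    return StimulusParams()


@pytest.fixture(scope="session")
def schedule_config():
    return ScheduleConfig()


@pytest.fixture(scope="session")
def small_session():
    """One small simulated-and-analyzed session shared across tests."""
    from attnvar.pipeline import SessionConfig, run_session_analysis, simulate_session

    cfg = SessionConfig(session_seed=42, n_units=6, n_trials=180,
                        schedule=ScheduleConfig(block_counted_trials=15),
                        n_perm_tuning=100, n_boot_psychometric=50)
    data = simulate_session(cfg)
    return data, run_session_analysis(data)
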