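import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mibci import SignalModel, feedback_paradigm, generate_session

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """One 40-trial feedback-style session (2 runs x 10 per class) with the
    default signal model; shared across tests that only need shapes."""
    paradigm = feedback_paradigm(n_runs=2, trials_per_class_per_run=10)
    return generate_session(paradigm, SignalModel(), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
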