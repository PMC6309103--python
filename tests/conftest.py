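import numpy as np
import pytest

from clockvar import synthetic


@pytest.fixture
def quiet_participant():
    """Deterministic participant: no clock noise, no drift, no motor noise."""
    return synthetic.ParticipantParams(
        "quiet",
        clock_cv=0.0,
        mu_one_second=1.0,
        drift_slope=0.0,
        startup_mean_factor=1.0,
        startup_cv_factor=1.0,
        motor_cv=0.0,
    )


@pytest.fixture
def typical_participant():
    return synthetic.ParticipantParams(
        "typ", clock_cv=0.12, mu_one_second=0.95, drift_slope=-0.01
    )


@pytest.fixture
def small_cohort():
    """A 16-participant cohort with trial tables, for integration-style tests."""
    participants = synthetic.sample_participants(16, seed=11)
    prod, repr_ = synthetic.simulate_cohort(participants, seed=12)
    return participants, prod, repr_
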