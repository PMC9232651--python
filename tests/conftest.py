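import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import magest as mg

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iid_reference() -> mg.StimulusSequence:
    """A duration-like i.i.d. reference sequence (ms)."""
    return mg.gen_iid_sequence(1000, mean=1150, sd=300, bounds=(400, 1900), seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Three subjects, 200 trials, walk + randomized conditions."""
    trials, manifest = mg.make_synthetic_study(
        {"n_subjects": 3, "n_trials": 200, "seed": 7}
    )
    return trials, manifest


@pytest.fixture(scope="session")
def noiseless_observer_trials() -> mg.TrialSequence:
    """Two-state observer with known parameters, no response noise."""
    truth = mg.ObserverParams("two_state", v_over_r=1.0, q_over_r=0.3, delta_x=0.02)
    stim = mg.gen_iid_sequence(400, 1150, 300, (400, 1900), seed=21)
    return mg.simulate_observer(stim, truth, response_noise_sd=0.0, seed=0)


def by_subject(trials):
    out = {}
    for t in trials:
        out.setdefault(t.subject_id, {})[t.condition] = t
    return out
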