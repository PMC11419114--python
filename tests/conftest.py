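import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fearetho as fe

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def moderate_dataset() -> fe.Dataset:
    """The default synthetic experiment: 32 rats, 2 sessions, moderate effect."""
    return fe.simulate_experiment(fe.SimConfig(seed=1))


@pytest.fixture(scope="session")
def session_stack(moderate_dataset):
    """(arrays, labels, meta) for the 64 session ethograms of the default run."""
    eths = fe.session_arrays(moderate_dataset.trials)
    return fe.stack_sessions(eths)


@pytest.fixture(scope="session")
def comparison_trials():
    """8 trials scored by 6 synthetic observers (the 696-frame comparison set)."""
    return fe.simulate_comparison_trials(fe.SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_trial(labels=None, **kw):
    """Handmade TrialFrames with sane defaults for unit tests."""
    defaults = dict(
        rat_id="r01",
        session_id="s1",
        session_type="conditioning",
        trial_index=1,
        group="paired",
        sex="female",
        intensity_mA=0.5,
        labels=tuple(labels) if labels is not None else ("background",) * 87,
    )
    defaults.update(kw)
    return fe.TrialFrames(**defaults)
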