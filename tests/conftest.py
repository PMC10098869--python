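import numpy as np
import pytest

from trajdec import synthgen


@pytest.fixture(scope="session")
def small_leadfield():
    return synthgen.gen_leadfield(n_channels=16, n_locations=84, seed=11)


@pytest.fixture(scope="session")
def tiny_design():
    return synthgen.StudyDesign(
        n_participants=3,
        n_sessions=2,
        n_trials_per_block=2,
        trial_duration_s=10.0,
        n_channels=16,
        n_locations=84,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_design):
    return synthgen.gen_study(tiny_design, "shared", snr_db=10.0, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
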