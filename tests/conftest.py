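import numpy as np
import pytest

from lumbarfc import SimParams, simulate_subject


@pytest.fixture(scope="session")
def small_params():
    """A fast cohort configuration: 3 slices, 160 volumes (large enough that
    the 32-column physiological design does not saturate the half-run
    pass-band), default noise regime."""
    return SimParams(n_subjects=4, n_slices=3, n_volumes=160, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_params):
    """(run, masks, recording, motion, truth) for one simulated subject."""
    return simulate_subject(small_params, 0)


@pytest.fixture(scope="session")
def noiseless_subject():
    """A subject whose horn voxels carry only the neural latents."""
    params = SimParams(
        n_subjects=1,
        n_slices=3,
        n_volumes=120,
        physio_weight=0.0,
        csf_weight=0.0,
        motion_weight=0.0,
        thermal_sd=0.0,
        seed=5,
    )
    return simulate_subject(params, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
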