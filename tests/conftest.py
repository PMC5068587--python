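import numpy as np
import pytest

from gcsr.synthetic_data import (
    CohortConfig,
    ConflictInjection,
    EEGParams,
    ResponderModel,
    generate_participant,
    simulate_behavior,
    simulate_pretest,
)
from gcsr.task_design import build_session_schedule


@pytest.fixture(scope="session")
def default_model():
    return ResponderModel()


@pytest.fixture(scope="session")
def one_block_behavior(default_model):
    """One simulated 128-trial session (behaviour only)."""
    rng = np.random.default_rng(7)
    pretest = simulate_pretest(default_model, rng)
    schedule = build_session_schedule(n_blocks=1, seed=7, pretest_go_rt_ms=pretest)
    return simulate_behavior(schedule, default_model, rng)


@pytest.fixture(scope="session")
def participant_with_eeg():
    """One fully synthesized participant (1 block, default EEG + injection)."""
    cfg = CohortConfig(
        groups={"placebo": 1},
        n_blocks=1,
        seed=21,
        injection=ConflictInjection(block_profile=(1.0,)),
    )
    rng = np.random.default_rng(np.random.SeedSequence(21))
    return generate_participant("placebo_00", "placebo", cfg, rng)


@pytest.fixture
def clean_eeg_params():
    """EEG parameters with every nuisance source switched off."""
    return EEGParams(pink_noise_scale=0.0, mains_amp=0.0, blink_rate_per_min=0.0)
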