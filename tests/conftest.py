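import numpy as np
import pytest

from shuttlesim import (
    FishAgentParams,
    PopulationParams,
    TrialConfig,
    generate_cohort,
    simulate_trial,
)


@pytest.fixture(scope="session")
def short_cfg() -> TrialConfig:
    """Abbreviated protocol (5/15/5/30 min) for fast simulation tests; same
    controller settings as the full protocol."""
    return TrialConfig(
        phase_durations={"habituation": 5, "ramping": 15, "gas": 5, "test": 30}
    )


@pytest.fixture(scope="session")
def default_agent() -> FishAgentParams:
    return FishAgentParams(set_point=27.3)


@pytest.fixture(scope="session")
def short_trial(short_cfg, default_agent):
    return simulate_trial(short_cfg, default_agent, seed=7)


@pytest.fixture(scope="session")
def small_cohort(short_cfg):
    """Six-fish cohort (3 control, 3 treated) on the abbreviated protocol."""
    pop = PopulationParams(
        between_fish_sd=1.0,
        within_fish_sd=0.0,
        n_control=3,
        n_treated=3,
        quiescence_hazard_treated=0.0,
    )
    tracks, truth = generate_cohort(pop, short_cfg, seed=11)
    return tracks, truth


@pytest.fixture(scope="session")
def full_trial_track(default_agent):
    """One full-length (7.5 h) trial at the default protocol."""
    return simulate_trial(TrialConfig(), default_agent, seed=1)
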