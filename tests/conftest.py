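import numpy as np
import pandas as pd
import pytest

from reachbias import experiment_config
from reachbias import synthetic as syn


@pytest.fixture(scope="session")
def cfg1():
    return experiment_config(1, sampling_rate_hz=100)


@pytest.fixture(scope="session")
def cfg2():
    return experiment_config(2, sampling_rate_hz=100)


@pytest.fixture(scope="session")
def cfg3():
    return experiment_config(3, sampling_rate_hz=100)


def line_trajectory(angle_deg, distance_cm=25.0, duration_ms=500.0, dt_ms=10.0, hold_ms=100.0):
    """Constant-speed straight path from the origin at a lab-frame angle,
    after a stationary hold (gives onset detection something to find)."""
    n_hold = int(hold_ms / dt_ms)
    n_move = int(duration_ms / dt_ms)
    t = np.arange(n_hold + n_move + 1) * dt_ms
    s = np.concatenate([np.zeros(n_hold), np.linspace(0, distance_cm, n_move + 1)])
    a = np.deg2rad(angle_deg)
    return np.column_stack([t, s * np.sin(a), s * np.cos(a)])


@pytest.fixture(scope="session")
def small_session(cfg1):
    profile = syn.ParticipantProfile(motor_sd_deg=1.0)
    design = syn.SessionDesign(
        experiment_id=1,
        blocks=(
            syn.Block(reward_ratio=2.0, likelihood_ratio=1.0, rewarded_side="R", n_trials=4),
            syn.Block(reward_ratio=1.0, likelihood_ratio=5.0, rewarded_side="L", n_trials=4),
        ),
    )
    return syn.simulate_session(profile, design, cfg1, seed=42, participant_id="P00")
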